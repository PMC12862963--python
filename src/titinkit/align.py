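"""Global pairwise alignment, percent identity and identity-matrix summaries.

All similarity values in the pipeline derive from optimal global alignment
with affine gap penalties.  The default scheme is BLOSUM62 with gap open 10,
gap extend 0.5 and free terminal gaps — suited to domain-region sequences of
unequal trimming.  Percent identity is computed over columns where both
sequences are non-gap; the ambiguity code X scores 0 against everything and
never counts as identical.

The dynamic-programming engine is Bio.Align.PairwiseAligner; this module
wraps it behind the pipeline's scoring and identity conventions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import SeqRecord, SequenceSet

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "IdentitySummary",
    "global_align",
    "score_pair",
    "identity_matrix",
    "identity_summary",
]


@lru_cache(maxsize=8)
def _matrix(name: str):
    mat = substitution_matrices.load(name).copy()
    # X is an ambiguity code, not evidence: zero score against everything.
    if "X" in mat.alphabet:
        i = mat.alphabet.index("X")
        mat[i, :] = 0.0
        mat[:, i] = 0.0
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring scheme for global alignment.

    ``terminal_gap_policy`` is ``"free"`` (terminal gaps cost nothing) or
    ``"penalized"`` (terminal gaps cost like internal ones).  A gap of length
    L costs ``gap_open + (L - 1) * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    terminal_gap_policy: str = "free"

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.terminal_gap_policy not in ("free", "penalized"):
            raise ValueError("terminal_gap_policy must be 'free' or 'penalized'")

    @property
    def substitution(self):
        """The (symmetric) substitution score table."""
        return _matrix(self.matrix_name)

    def score(self, a: str, b: str) -> float:
        """Substitution score of a residue pair."""
        return float(self.substitution[a, b])

    def aligner(self) -> Align.PairwiseAligner:
        return _aligner(self)


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _matrix(scheme.matrix_name)
    al.open_gap_score = -scheme.gap_open
    al.extend_gap_score = -scheme.gap_extend
    if scheme.terminal_gap_policy == "free":
        al.open_end_gap_score = 0.0
        al.extend_end_gap_score = 0.0
    return al


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal global alignment of two sequences.

    ``identity_pct`` = 100 * n_identical / n_aligned_columns, counted over
    columns where both positions are non-gap.
    """

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    n_aligned_columns: int

    @property
    def identity_pct(self) -> float:
        if self.n_aligned_columns == 0:
            return float("nan")
        return 100.0 * self.n_identical / self.n_aligned_columns


def _as_seq(x: SeqRecord | str) -> tuple[str, str]:
    if isinstance(x, SeqRecord):
        return x.id, x.residues
    return "", str(x)


def global_align(
    a: SeqRecord | str, b: SeqRecord | str, scheme: ScoringScheme | None = None
) -> AlignmentResult:
    """Optimal global alignment of two sequences under ``scheme``.

    Traceback is deterministic (the aligner's first optimal path).  Raises
    ``ValueError`` on an empty sequence.
    """
    scheme = scheme or DEFAULT_SCHEME
    id_a, seq_a = _as_seq(a)
    id_b, seq_b = _as_seq(b)
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    # canonical argument order makes the tie-broken traceback — and hence
    # identity — exactly symmetric in the inputs
    if seq_b < seq_a:
        aln = scheme.aligner().align(seq_b, seq_a)[0]
        ga, gb = str(aln[1]), str(aln[0])
    else:
        aln = scheme.aligner().align(seq_a, seq_b)[0]
        ga, gb = str(aln[0]), str(aln[1])
    n_cols = n_id = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            n_cols += 1
            if x == y and x != "X":
                n_id += 1
    return AlignmentResult(
        id_a=id_a,
        id_b=id_b,
        aligned_a=ga,
        aligned_b=gb,
        score=float(aln.score),
        n_identical=n_id,
        n_aligned_columns=n_cols,
    )


def score_pair(
    a: SeqRecord | str, b: SeqRecord | str, scheme: ScoringScheme | None = None
) -> float:
    """Optimal global alignment score only (no traceback; fast path)."""
    scheme = scheme or DEFAULT_SCHEME
    _, seq_a = _as_seq(a)
    _, seq_b = _as_seq(b)
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    return float(scheme.aligner().score(seq_a, seq_b))


@dataclass(frozen=True)
class IdentitySummary:
    """Within-group identity over all unordered pairs: mean +/- sd and range.

    A group of size 1 has no pairs; its statistics are ``None`` (undefined),
    never zero.
    """

    group: str
    n_sequences: int
    n_pairs: int
    mean_pct: float | None
    sd_pct: float | None
    min_pct: float | None
    max_pct: float | None


def identity_matrix(
    sset: SequenceSet | Sequence[SeqRecord], scheme: ScoringScheme | None = None
) -> pd.DataFrame:
    """Square matrix of pairwise percent identities (diagonal 100)."""
    records = list(sset)
    ids = [r.id for r in records]
    n = len(records)
    mat = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        pct = global_align(records[i], records[j], scheme).identity_pct
        mat[i, j] = mat[j, i] = pct
    return pd.DataFrame(mat, index=ids, columns=ids)


def identity_summary(
    sset: SequenceSet,
    group_by: str = "group",
    scheme: ScoringScheme | None = None,
    representatives: dict[str, str] | None = None,
) -> tuple[list[IdentitySummary], pd.DataFrame]:
    """Per-group identity summaries and the symmetric cross-group matrix.

    Within-group statistics run over all unordered pairs of the group.
    Cross-group entries average identity over all between-group pairs, or —
    when ``representatives`` maps group -> sequence id — over the designated
    representative pair only.
    """
    idm = identity_matrix(sset, scheme)
    groups = sset.groups(group_by)
    names = sorted(groups)

    summaries: list[IdentitySummary] = []
    for g in names:
        ids = [r.id for r in groups[g]]
        vals = [
            idm.loc[x, y] for x, y in itertools.combinations(ids, 2)
        ]
        if vals:
            arr = np.asarray(vals)
            summaries.append(
                IdentitySummary(
                    group=g,
                    n_sequences=len(ids),
                    n_pairs=len(vals),
                    mean_pct=float(arr.mean()),
                    sd_pct=float(arr.std(ddof=1)) if len(vals) > 1 else 0.0,
                    min_pct=float(arr.min()),
                    max_pct=float(arr.max()),
                )
            )
        else:
            summaries.append(
                IdentitySummary(g, len(ids), 0, None, None, None, None)
            )

    cross = pd.DataFrame(np.nan, index=names, columns=names)
    for ga, gb in itertools.combinations_with_replacement(names, 2):
        if representatives and ga in representatives and gb in representatives:
            val = float(idm.loc[representatives[ga], representatives[gb]])
        else:
            ids_a = [r.id for r in groups[ga]]
            ids_b = [r.id for r in groups[gb]]
            if ga == gb:
                pairs = list(itertools.combinations(ids_a, 2))
            else:
                pairs = [(x, y) for x in ids_a for y in ids_b]
            if not pairs:
                continue
            val = float(np.mean([idm.loc[x, y] for x, y in pairs]))
        cross.loc[ga, gb] = cross.loc[gb, ga] = val
    return summaries, cross
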