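"""Reference-anchored extraction and quantification of TK signature motifs.

The titin-kinase region carries a pseudokinase signature: a θxK motif in
strand β3 (θ a bulky hydrophobic residue instead of the canonical small one),
an ExG motif in the magnesium-binding slot (instead of DFG), an [N/L]YD
anchor in the N-terminal linker, and — in the C-terminal regulatory domain —
an [R/K]H[R/K]RYY helix-αR1 motif, an R-7x-R motif, and a small residue at
position −2 of R-7x-R that packs against θ and completes the catalytic spine.
The bulk of θ anti-correlates with the size of the −2 residue (volume
compensation), which this module quantifies as a 2×2 association.

Sequences are mapped column-wise onto an annotated reference by global
alignment; anchored features are read off mapped columns, pattern-based
features are found by scanning the NL/CRD windows.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import ScoringScheme, global_align
from .seq_io import Labels, SeqRecord

__all__ = [
    "ReferenceAnnotation",
    "ColumnMap",
    "MotifSignature",
    "GroupFrequencyTable",
    "CovariationResult",
    "UnmappableError",
    "map_columns",
    "extract_signature",
    "group_frequencies",
    "covariation",
    "BULKY",
    "SMALL",
    "LARGE",
]

# Residue classes of the covariation analysis.  V is deliberately excluded
# from SMALL: at position -2 valine is tallied separately, not as "small".
BULKY = frozenset("MLIF")
SMALL = frozenset("GAST")
LARGE = frozenset("LIVMF")

GLY_LOOP_TEMPLATES = {
    "GxGxxG": re.compile(r"G.G..G"),
    "RxGxxG": re.compile(r"R.G..G"),
    "Ax[C/S]xxG": re.compile(r"A.[CS]..G"),
}

_YD_RE = re.compile(r"[NL]YD")
_ALPHAR1_RE = re.compile(r"[RK]H[RK]RYY")
_R7XR_RE = re.compile(r"R(?=.{7}R)")


class UnmappableError(ValueError):
    """Query cannot be mapped onto the reference (identity below floor)."""


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Named anchor positions on a reference TK-region sequence.

    Positions are 1-based in the reference's local numbering frame (for the
    medaka ttnb construct, residue 1 is the parent-protein M27887).  Windows
    are inclusive (start, end) spans.
    """

    reference: SeqRecord
    gly_rich_loop: tuple[int, ...]        # 6-position window, canonical GxGxxG
    beta3_theta: int                      # position 1 of the θxK motif
    beta3_lysine: int                     # catalytic lysine (K68 in medTKb)
    alphaC_glutamate: int                 # E83
    catalytic_aspartate: int              # D159 medTKb / D144 human
    dfg_slot: tuple[int, int, int]        # canonical DFG; ELG in medTKb
    p_plus1: int                          # Y187 human / A202 medTKb
    nl_window: tuple[int, int]            # NL span (~33 residues)
    crd_window: tuple[int, int]           # CRD span
    c_spine: tuple[int, ...]
    r_spine: tuple[int, ...]
    yd: tuple[int, int]                   # the YD motif itself (Y12, D13)
    yd_contacts: tuple[int, ...]          # E43, S116, R170
    r7xr_first: int                       # R330
    r7xr_second: int                      # R338
    minus2: int                           # A328
    hinge_acids: tuple[int, ...]          # D119, D122

    def __post_init__(self) -> None:
        n = len(self.reference)
        for pos in self.all_positions():
            if not (1 <= pos <= n):
                raise ValueError(f"anchor position {pos} outside reference (len {n})")
        if not (
            self.nl_window[1] < self.gly_rich_loop[0]
            and self.p_plus1 < self.crd_window[0]
        ):
            raise ValueError("windows must be ordered NL < kinase < CRD")

    def all_positions(self) -> list[int]:
        out: list[int] = []
        out += list(self.gly_rich_loop)
        out += [
            self.beta3_theta,
            self.beta3_lysine,
            self.alphaC_glutamate,
            self.catalytic_aspartate,
            self.p_plus1,
            self.r7xr_first,
            self.r7xr_second,
            self.minus2,
        ]
        out += list(self.dfg_slot) + list(self.c_spine) + list(self.r_spine)
        out += list(self.yd) + list(self.yd_contacts) + list(self.hinge_acids)
        out += list(self.nl_window) + list(self.crd_window)
        return out

    def kinase_anchor_names(self) -> list[str]:
        """Anchors defining "full kinase region" coverage (gly loop → P+1)."""
        return [
            "gly_rich_loop",
            "beta3_theta",
            "beta3_lysine",
            "alphaC_glutamate",
            "catalytic_aspartate",
            "dfg_slot",
            "p_plus1",
        ]

    def anchor_positions(self, name: str) -> tuple[int, ...]:
        val = getattr(self, name)
        if isinstance(val, int):
            return (val,)
        return tuple(val)

    def kinase_anchor_positions(self) -> list[int]:
        out: list[int] = []
        for name in self.kinase_anchor_names():
            out += list(self.anchor_positions(name))
        return out

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["reference"] = {
            "id": self.reference.id,
            "residues": self.reference.residues,
            "description": self.reference.description,
            "labels": asdict(self.reference.labels),
            "local_numbering_offset": self.reference.local_numbering_offset,
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceAnnotation":
        d = json.loads(Path(path).read_text())
        ref = d.pop("reference")
        rec = SeqRecord(
            id=ref["id"],
            residues=ref["residues"],
            description=ref.get("description", ""),
            labels=Labels(**ref.get("labels", {})),
            local_numbering_offset=ref.get("local_numbering_offset", 1),
        )
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
        }
        return cls(reference=rec, **kwargs)


@dataclass
class ColumnMap:
    """Mapping from reference positions to query positions (both 1-based).

    ``ref_to_query[p]`` is the query position aligned to reference position
    ``p + 1``, or ``None`` for a gap.  The mapping is strictly increasing
    over mapped positions (it derives from one global alignment).
    """

    query_id: str
    ref_id: str
    ref_to_query: list[int | None]
    identity_pct: float
    coverage: dict[str, bool]

    def query_position(self, ref_pos: int) -> int | None:
        return self.ref_to_query[ref_pos - 1]

    def covers(self, anchor_names: Sequence[str]) -> bool:
        return all(self.coverage.get(name, False) for name in anchor_names)

    def window_string(self, query: SeqRecord, start: int, end: int) -> str:
        """Query residues over a reference window; '-' marks gapped columns."""
        out = []
        for p in range(start, end + 1):
            q = self.query_position(p)
            out.append(query.residues[q - 1] if q is not None else "-")
        return "".join(out)


ANCHOR_FIELDS = (
    "gly_rich_loop",
    "beta3_theta",
    "beta3_lysine",
    "alphaC_glutamate",
    "catalytic_aspartate",
    "dfg_slot",
    "p_plus1",
    "nl_window",
    "crd_window",
    "c_spine",
    "r_spine",
    "yd",
    "yd_contacts",
    "r7xr_first",
    "r7xr_second",
    "minus2",
    "hinge_acids",
)


def map_columns(
    query: SeqRecord,
    ref: ReferenceAnnotation,
    scheme: ScoringScheme | None = None,
    min_identity_pct: float = 25.0,
) -> ColumnMap:
    """Map query positions onto the reference by one global alignment.

    Raises :class:`UnmappableError` when alignment identity falls below the
    floor (default 25%), preventing nonsense motif calls on unrelated input.
    """
    res = global_align(ref.reference, query, scheme)
    if res.n_aligned_columns == 0 or res.identity_pct < min_identity_pct:
        raise UnmappableError(
            f"{query.id!r} aligns to {ref.reference.id!r} at "
            f"{res.identity_pct:.1f}% identity (< {min_identity_pct}%)"
        )
    ref_to_query: list[int | None] = []
    qpos = 0
    for rc, qc in zip(res.aligned_a, res.aligned_b):
        if qc != "-":
            qpos += 1
        if rc != "-":
            ref_to_query.append(qpos if qc != "-" else None)
    coverage = {
        name: all(
            ref_to_query[p - 1] is not None for p in ref.anchor_positions(name)
        )
        for name in ANCHOR_FIELDS
    }
    return ColumnMap(
        query_id=query.id,
        ref_id=ref.reference.id,
        ref_to_query=ref_to_query,
        identity_pct=res.identity_pct,
        coverage=coverage,
    )


def _classify(residue: str | None, members: frozenset, other_members: frozenset,
              name_a: str, name_b: str) -> str | None:
    if residue is None:
        return None
    if residue in members:
        return name_a
    if residue in other_members:
        return name_b
    return "other"


@dataclass
class MotifSignature:
    """Signature residues of one sequence, read off the reference frame.

    Absent motifs are recorded as ``None`` — absence is a value, never a
    guess.  Classes derive only from the fixed residue sets BULKY / SMALL /
    LARGE.
    """

    id: str
    gly_loop_pattern: str | None = None
    gly_loop_template: str | None = None
    theta_residue: str | None = None
    theta_class: str | None = None
    dfg_slot_string: str | None = None
    dfg_first_residue: str | None = None   # "D", "E" or "other"
    p_plus1_residue: str | None = None
    yd_match: str | None = None            # matched [N/L]YD pattern
    yd_preceding: str | None = None        # residue before the YD pair
    crd_alphaR1: str | None = None         # matched [R/K]H[R/K]RYY or None
    r7xr: tuple[int, int] | None = None    # query positions of the two R's
    r7xr_multiple: bool = False            # several matches; first taken
    minus2_residue: str | None = None
    minus2_class: str | None = None


def extract_signature(
    query: SeqRecord, cmap: ColumnMap, ref: ReferenceAnnotation
) -> MotifSignature:
    """Extract the TK signature motifs of one sequence.

    Anchored fields (θ, DFG slot, P+1, gly-loop window, −2 fallback) are read
    off mapped columns; pattern-based fields ([N/L]YD, [R/K]H[R/K]RYY,
    R-7x-R) are found by scanning the NL/CRD windows of the query.  The
    residue at position −2 is taken two positions before the first R of the
    matched R-7x-R, falling back to the anchored column when no match exists.
    A pure per-sequence function: independent of any other sequence.
    """
    sig = MotifSignature(id=query.id)
    seq = query.residues

    def mapped_residue(ref_pos: int) -> str | None:
        q = cmap.query_position(ref_pos)
        return seq[q - 1] if q is not None else None

    if cmap.coverage.get("gly_rich_loop"):
        window = cmap.window_string(
            query, ref.gly_rich_loop[0], ref.gly_rich_loop[-1]
        )
        sig.gly_loop_pattern = window
        # templates are mutually exclusive in their first position
        matched = [
            name for name, rx in GLY_LOOP_TEMPLATES.items() if rx.fullmatch(window)
        ]
        sig.gly_loop_template = matched[0] if matched else "other"

    if cmap.coverage.get("beta3_theta"):
        sig.theta_residue = mapped_residue(ref.beta3_theta)
        sig.theta_class = _classify(sig.theta_residue, BULKY, SMALL, "bulky", "small")

    if cmap.coverage.get("dfg_slot"):
        sig.dfg_slot_string = cmap.window_string(
            query, ref.dfg_slot[0], ref.dfg_slot[-1]
        )
        first = sig.dfg_slot_string[0]
        sig.dfg_first_residue = first if first in "DE" else "other"

    if cmap.coverage.get("p_plus1"):
        sig.p_plus1_residue = mapped_residue(ref.p_plus1)

    # --- pattern scans in the query's own coordinates -----------------
    def window_span(window: tuple[int, int]) -> tuple[int, int] | None:
        qpos = [
            cmap.query_position(p)
            for p in range(window[0], window[1] + 1)
            if cmap.query_position(p) is not None
        ]
        if not qpos:
            return None
        return min(qpos), max(qpos)

    nl = window_span(ref.nl_window)
    if nl is not None:
        m = _YD_RE.search(seq, nl[0] - 1, nl[1])
        if m:
            sig.yd_match = m.group(0)
            sig.yd_preceding = m.group(0)[0]
        else:
            # YD without a canonical N/L in front still anchors the NL
            m2 = re.compile(r"YD").search(seq, nl[0] - 1, nl[1])
            if m2:
                sig.yd_match = "YD"
                sig.yd_preceding = seq[m2.start() - 1] if m2.start() > 0 else None

    crd = window_span(ref.crd_window)
    if crd is not None:
        m = _ALPHAR1_RE.search(seq, crd[0] - 1, crd[1])
        if m:
            sig.crd_alphaR1 = m.group(0)
        matches = list(_R7XR_RE.finditer(seq, crd[0] - 1, crd[1]))
        # the look-ahead second R must itself fall inside the CRD window
        matches = [m for m in matches if m.start() + 8 <= crd[1] - 1]
        if matches:
            first = matches[0]
            sig.r7xr = (first.start() + 1, first.start() + 9)  # 1-based
            sig.r7xr_multiple = len(matches) > 1
            mpos = first.start() - 2
            if mpos >= 0:
                sig.minus2_residue = seq[mpos]
    if sig.minus2_residue is None and cmap.coverage.get("minus2"):
        sig.minus2_residue = mapped_residue(ref.minus2)
    sig.minus2_class = _classify(sig.minus2_residue, SMALL, LARGE, "small", "large")
    return sig


TRACKED_FEATURES = (
    "gly_loop_template",
    "theta_residue",
    "theta_class",
    "dfg_first_residue",
    "p_plus1_residue",
    "yd_preceding",
    "crd_alphaR1",
    "minus2_residue",
    "minus2_class",
)


@dataclass
class GroupFrequencyTable:
    """Per-group residue/class frequencies at the tracked signature positions.

    ``counts[group][feature][value] = n``; percentages are over resolved
    sequences only, with per-feature exclusion counts reported.  Percentages
    per (group, feature) sum to 100 within rounding.
    """

    counts: dict[str, dict[str, dict[str, int]]]
    n_excluded: dict[str, dict[str, int]]
    group_sizes: dict[str, int]

    def pct(self, group: str, feature: str, value: str) -> float:
        table = self.counts[group][feature]
        total = sum(table.values())
        return 100.0 * table.get(value, 0) / total if total else float("nan")

    def count(self, group: str, feature: str, value: str) -> int:
        return self.counts[group][feature].get(value, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, feats in self.counts.items():
            for f, table in feats.items():
                total = sum(table.values())
                for val, n in sorted(table.items()):
                    rows.append(
                        {
                            "group": g,
                            "feature": f,
                            "value": val,
                            "count": n,
                            "pct": 100.0 * n / total if total else float("nan"),
                            "n_resolved": total,
                            "n_excluded": self.n_excluded[g][f],
                        }
                    )
        return pd.DataFrame(rows)


def group_frequencies(
    signatures: Sequence[MotifSignature],
    labels: Mapping[str, str],
) -> GroupFrequencyTable:
    """Per-group frequency of each tracked signature feature.

    ``labels`` maps sequence id -> group name (e.g. the cluster calls).
    Sequences with an unresolved feature are excluded from that feature's
    denominator; empty groups are omitted.
    """
    groups: dict[str, list[MotifSignature]] = {}
    for sig in signatures:
        g = labels.get(sig.id)
        if g is None:
            continue
        groups.setdefault(g, []).append(sig)

    counts: dict[str, dict[str, dict[str, int]]] = {}
    excluded: dict[str, dict[str, int]] = {}
    sizes: dict[str, int] = {}
    for g, sigs in groups.items():
        sizes[g] = len(sigs)
        counts[g] = {}
        excluded[g] = {}
        for feat in TRACKED_FEATURES:
            table: dict[str, int] = {}
            n_missing = 0
            for sig in sigs:
                val = getattr(sig, feat)
                if val is None:
                    n_missing += 1
                else:
                    table[val] = table.get(val, 0) + 1
            counts[g][feat] = table
            excluded[g][feat] = n_missing
    return GroupFrequencyTable(counts=counts, n_excluded=excluded, group_sizes=sizes)


@dataclass
class CovariationResult:
    """2x2 association between θ bulk and −2 smallness.

    ``counts[i][j]``: rows are θ (bulky, not bulky), columns are −2 (small,
    not small).  ``odds_ratio`` is Haldane-corrected (+0.5 per cell) when any
    cell is zero; ``association`` = sqrt(chi²/n) ∈ [0, 1] (phi for 2×2).
    """

    counts: np.ndarray
    n: int
    odds_ratio: float | None
    association: float | None
    undefined: bool = False


def covariation(signatures: Sequence[MotifSignature]) -> CovariationResult:
    """θ-class vs −2-class contingency over all resolved signatures."""
    resolved = [
        s for s in signatures
        if s.theta_class is not None and s.minus2_class is not None
    ]
    if len(resolved) < 2:
        raise ValueError("need >= 2 sequences with both motifs resolved")
    c = np.zeros((2, 2), dtype=int)
    for s in resolved:
        i = 0 if s.theta_class == "bulky" else 1
        j = 0 if s.minus2_class == "small" else 1
        c[i, j] += 1
    n = int(c.sum())
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    if 0 in row or 0 in col:
        return CovariationResult(c, n, None, None, undefined=True)
    cc = c.astype(float)
    if (cc == 0).any():
        cc = cc + 0.5
    odds = float(cc[0, 0] * cc[1, 1] / (cc[0, 1] * cc[1, 0]))
    chi2 = stats.chi2_contingency(c, correction=False)[0]
    phi = float(np.sqrt(chi2 / n))
    return CovariationResult(c, n, odds, min(phi, 1.0), undefined=False)
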