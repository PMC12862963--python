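"""Synthetic TK families and coordinate pairs with known ground truth.

The family generator emulates the study conditions of the TK comparison: a
five-group family (mammal, fish isoform a/b × neoteleostei/non-neoteleostei)
evolved on a fixed tree in which the isoform split is deeper than the clade
split, with group-specific signature-motif residues implanted at the
annotated anchor columns.  Default motif tables carry the per-group
percentages reported for the real clusters (θ methionine content, ExG vs DxG,
P+1 tyrosine, −2 composition, gly-loop templates); default branch rates are
chosen so expected identity levels mirror the published within-cluster
(~96%) and cross-cluster (~57–78%) ranges.

The coordinate generator emits rigid-transformed, noise-perturbed copies of
a random Cα trace with the analytically expected post-superposition RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import references
from .motifs import ReferenceAnnotation
from .seq_io import Labels, SeqRecord, SequenceSet
from .structure import Atom, Residue, StructureModel

__all__ = [
    "GROUPS",
    "SimConfig",
    "TruthTable",
    "simulate_families",
    "simulate_structure_pair",
    "default_motif_tables",
    "study_config",
]

GROUPS = (
    "mammal",
    "a/neoteleostei",
    "a/non-neoteleostei",
    "b/neoteleostei",
    "b/non-neoteleostei",
)

_GROUP_LABELS = {
    "mammal": Labels(taxon_class="mammal", fish_clade="none", isoform="none"),
    "a/neoteleostei": Labels("fish", "neoteleostei", "a"),
    "a/non-neoteleostei": Labels("fish", "non-neoteleostei", "a"),
    "b/neoteleostei": Labels("fish", "neoteleostei", "b"),
    "b/non-neoteleostei": Labels("fish", "non-neoteleostei", "b"),
}

_GROUP_PREFIX = {
    "mammal": "mam",
    "a/neoteleostei": "aneo",
    "a/non-neoteleostei": "anon",
    "b/neoteleostei": "bneo",
    "b/non-neoteleostei": "bnon",
}

#: Group sizes of the real study set (452 curated fish + mammal sequences).
STUDY_GROUP_SIZES = {
    "mammal": 139,
    "a/neoteleostei": 91,
    "b/neoteleostei": 100,
    "a/non-neoteleostei": 60,
    "b/non-neoteleostei": 62,
}


def _norm(table: Mapping[str, float]) -> dict[str, float]:
    total = sum(table.values())
    return {k: v / total for k, v in table.items()}


def default_motif_tables() -> dict[str, dict[str, dict[str, float]]]:
    """Per-group residue->probability tables at the variable anchors.

    Keys are feature names; positions come from the medTKb anchor frame.
    Percentages follow the reported per-cluster quantitation: θ methionine
    content per group (remainder split over L/I/F in their overall 8.7 / 0.6
    / 2.6 proportions), ExG vs DxG in the magnesium slot, P+1 tyrosine
    presence, the shared −2 composition, the [N/L]YD preceding residue, and
    the group-specific gly-loop template.
    """
    lif = _norm({"L": 8.7, "I": 0.6, "F": 2.6})

    def theta(m_pct: float) -> dict[str, float]:
        rest = 1.0 - m_pct / 100.0
        return _norm({"M": m_pct / 100.0, **{k: v * rest for k, v in lif.items()}})

    minus2 = _norm({"A": 76.8, "S": 7.6, "T": 7.6, "G": 4.8, "V": 1.5, "E": 0.4})
    yd_prev = _norm({"N": 73.8, "L": 26.2})
    tables: dict[str, dict[str, dict[str, float]]] = {
        "mammal": {
            "theta": theta(98.5),
            "dfg_first": {"E": 1.0},
            "dfg_mid": {"F": 1.0},
            "p_plus1": {"Y": 0.964, "A": 0.036},
            "gly_loop": {"GKGSFG": 1.0},
        },
        "a/neoteleostei": {
            "theta": theta(98.9),
            "dfg_first": {"E": 0.824, "D": 0.176},
            "dfg_mid": {"L": 1.0},
            "p_plus1": {"Y": 0.286, "A": 0.714},
            "gly_loop": {"AKCSFG": 0.5, "AKSSFG": 0.5},
        },
        "a/non-neoteleostei": {
            "theta": theta(40.0),
            "dfg_first": {"E": 0.933, "D": 0.067},
            "dfg_mid": {"L": 1.0},
            "p_plus1": {"Y": 0.467, "A": 0.533},
            "gly_loop": {"RKGSFG": 1.0},
        },
        "b/neoteleostei": {
            "theta": {"M": 1.0},
            "dfg_first": {"E": 1.0},
            "dfg_mid": {"L": 1.0},
            "p_plus1": {"A": 1.0},
            "gly_loop": {"GKGSFG": 1.0},
        },
        "b/non-neoteleostei": {
            "theta": theta(77.4),
            "dfg_first": {"E": 1.0},
            "dfg_mid": {"L": 1.0},
            "p_plus1": {"A": 1.0},
            "gly_loop": {"GKGSFG": 1.0},
        },
    }
    for group in tables:
        tables[group]["minus2"] = dict(minus2)
        tables[group]["yd_prev"] = dict(yd_prev)
    return tables


#: Feature name -> 1-based anchor position(s) in the medTKb frame.
FEATURE_POSITIONS: dict[str, tuple[int, ...]] = {
    "theta": (66,),
    "dfg_first": (179,),
    "dfg_mid": (180,),
    "p_plus1": (202,),
    "minus2": (328,),
    "yd_prev": (11,),
    "gly_loop": (45, 46, 47, 48, 49, 50),
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the family simulator; the seed fully determines output.

    Branch rates are per-site substitution probabilities on each tree edge:
    root → (mammal, fish); fish → (isoform a, isoform b); isoform →
    (neoteleostei, non-neoteleostei); plus a terminal per-sequence rate.  The
    isoform rate is strictly larger than the clade rate by default, making
    the isoform split the deeper divergence.
    """

    seed: int = 0
    root_length: int = 355
    rate_root: float = 0.30
    rate_isoform: float = 0.22
    rate_clade: float = 0.09
    rate_terminal: float = 0.02
    n_per_group: int | Mapping[str, int] = 20
    motif_tables: dict | None = None
    truncation_fraction: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.rate_root, self.rate_isoform, self.rate_clade,
                  self.rate_terminal):
            if r < 0:
                raise ValueError("branch rates must be >= 0")
        if not (0.0 <= self.truncation_fraction < 1.0):
            raise ValueError("truncation_fraction in [0, 1)")

    def group_sizes(self) -> dict[str, int]:
        if isinstance(self.n_per_group, Mapping):
            return {g: int(self.n_per_group.get(g, 0)) for g in GROUPS}
        return {g: int(self.n_per_group) for g in GROUPS}

    def tables(self) -> dict:
        tables = self.motif_tables or default_motif_tables()
        for group, feats in tables.items():
            for feat in feats:
                if feat not in FEATURE_POSITIONS:
                    raise ValueError(f"motif table references unknown anchor {feat!r}")
                for res_table in [feats[feat]]:
                    total = sum(res_table.values())
                    if abs(total - 1.0) > 1e-6:
                        raise ValueError(
                            f"probabilities for {group}/{feat} sum to {total}"
                        )
        return tables


def study_config(seed: int = 0, **kwargs) -> SimConfig:
    """A SimConfig with the real study's per-group sample sizes."""
    return SimConfig(seed=seed, n_per_group=dict(STUDY_GROUP_SIZES), **kwargs)


@dataclass
class TruthTable:
    """Ground truth of a simulated family set.

    ``per_sequence`` has one row per emitted record (group labels, ancestor
    id, truncation flag and the implanted residue of every variable anchor);
    realized per-group motif frequencies derive from it.  ``reference`` is
    the annotation frame of this simulation: the simulated root sequence
    with the canonical anchor residues implanted — every emitted sequence is
    homologous to it, as the real sequence sets are to the medTKb reference.
    """

    per_sequence: pd.DataFrame
    reference: "ReferenceAnnotation | None" = None

    def realized_frequency(self, group: str, feature: str, value: str) -> float:
        sub = self.per_sequence[self.per_sequence["group"] == group]
        if len(sub) == 0:
            return float("nan")
        return float((sub[feature] == value).mean())

    def implanted(self, rec_id: str, feature: str) -> str:
        return self.per_sequence.set_index("id").loc[rec_id, feature]

    @property
    def groups(self) -> dict[str, str]:
        return dict(zip(self.per_sequence["id"], self.per_sequence["group"]))


def _mutate(seq: np.ndarray, rate: float, alphabets: list[str],
            rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution with probability ``rate``.

    Replacements are drawn uniformly from the position's background alphabet
    (draws may silently coincide with the current residue).
    """
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = rng.choice(list(alphabets[i]))
    return out


def _sample(table: Mapping[str, float], rng: np.random.Generator) -> str:
    keys = sorted(table)
    probs = np.array([table[k] for k in keys])
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def simulate_families(cfg: SimConfig) -> tuple[SequenceSet, TruthTable]:
    """Simulate the five-group TK family with implanted signature motifs.

    An ancestor is drawn uniformly over the position-specific background
    alphabets; group ancestors arise by per-site substitution along the tree
    (root → mammal/fish → isoform → clade); each sequence adds terminal
    substitutions, then every anchor column is overwritten — fixed anchors
    from the canonical reference residues, variable anchors sampled from the
    group's motif table.  FASTA headers carry the truth labels.  With
    ``truncation_fraction > 0``, that fraction of sequences (spread over
    groups) is truncated mid-kinase so it no longer covers the kinase-domain
    anchors.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.root_length
    alphabets = [references.backbone_alphabet(p) for p in range(1, L + 1)]
    tables = cfg.tables()
    sizes = cfg.group_sizes()

    fixed_anchor = {
        pos: res
        for pos, res in references.CANONICAL_RESIDUES.items()
        if pos <= L
    }
    variable_positions = {
        pos for feat, positions in FEATURE_POSITIONS.items() for pos in positions
    }

    root = np.array([rng.choice(list(a)) for a in alphabets])
    ref_residues = root.copy()
    for pos, res in fixed_anchor.items():
        ref_residues[pos - 1] = res
    reference = ReferenceAnnotation(
        reference=SeqRecord(
            id="sim_root_reference",
            residues="".join(ref_residues),
            description="simulated root with canonical anchor residues "
            "(annotation frame of this simulation)",
        ),
        **{k: v for k, v in references.MEDTKB_ANCHORS.items()},
    )
    mammal_anc = _mutate(root, cfg.rate_root, alphabets, rng)
    fish_anc = _mutate(root, cfg.rate_root, alphabets, rng)
    iso_anc = {
        "a": _mutate(fish_anc, cfg.rate_isoform, alphabets, rng),
        "b": _mutate(fish_anc, cfg.rate_isoform, alphabets, rng),
    }
    group_anc: dict[str, np.ndarray] = {"mammal": mammal_anc}
    for iso in ("a", "b"):
        for clade in ("neoteleostei", "non-neoteleostei"):
            group_anc[f"{iso}/{clade}"] = _mutate(
                iso_anc[iso], cfg.rate_clade, alphabets, rng
            )

    records: list[SeqRecord] = []
    rows: list[dict] = []
    for group in GROUPS:
        n = sizes[group]
        lab = _GROUP_LABELS[group]
        prefix = _GROUP_PREFIX[group]
        for i in range(n):
            seq = _mutate(group_anc[group], cfg.rate_terminal, alphabets, rng)
            # fixed conserved anchors (catalytic core, spines, motifs)
            for pos, res in fixed_anchor.items():
                if pos not in variable_positions:
                    seq[pos - 1] = res
            # group-specific variable anchors
            implanted: dict[str, str] = {}
            for feat, positions in FEATURE_POSITIONS.items():
                drawn = _sample(tables[group][feat], rng)
                if len(positions) == 1:
                    seq[positions[0] - 1] = drawn
                else:
                    for pos, res in zip(positions, drawn):
                        seq[pos - 1] = res
                implanted[feat] = drawn
            rec_id = f"{prefix}{i + 1:03d}"
            records.append(
                SeqRecord(
                    id=rec_id,
                    residues="".join(seq),
                    description=(
                        f"group={group} taxon_class={lab.taxon_class} "
                        f"clade={lab.fish_clade} isoform={lab.isoform}"
                    ),
                    labels=lab,
                )
            )
            rows.append(
                {
                    "id": rec_id,
                    "group": group,
                    "taxon_class": lab.taxon_class,
                    "fish_clade": lab.fish_clade,
                    "isoform": lab.isoform,
                    "ancestor": group,
                    "truncated": False,
                    **implanted,
                }
            )

    if cfg.truncation_fraction > 0:
        n_trunc = int(round(cfg.truncation_fraction * len(records)))
        cut = 150  # mid-kinase: drops catalytic loop, ExG slot and P+1
        chosen = rng.choice(len(records), size=n_trunc, replace=False)
        for idx in sorted(int(i) for i in chosen):
            rec = records[idx]
            records[idx] = replace(rec, residues=rec.residues[:cut])
            rows[idx]["truncated"] = True

    truth = TruthTable(per_sequence=pd.DataFrame(rows), reference=reference)
    sset = SequenceSet(records, provenance=f"simulate_families(seed={cfg.seed})")
    return sset, truth


def default_anchor_ids(truth: TruthTable) -> dict[str, Labels]:
    """One labelled anchor per group (the first simulated sequence of each)."""
    out: dict[str, Labels] = {}
    for group in GROUPS:
        sub = truth.per_sequence[truth.per_sequence["group"] == group]
        if len(sub):
            out[sub.iloc[0]["id"]] = _GROUP_LABELS[group]
    return out


def simulate_structure_pair(
    seed: int,
    n_points: int = 150,
    noise_sigma: float = 0.5,
    transform: tuple[np.ndarray, np.ndarray] | None = None,
    mirror: bool = False,
) -> tuple[StructureModel, StructureModel, float]:
    """A Cα-trace model and a rigid-transformed, noise-perturbed copy.

    The second model is ``R @ x + t`` plus isotropic Gaussian noise of
    standard deviation ``noise_sigma`` per coordinate; with ``mirror=True``
    the copy is additionally reflected (to exercise the reflection guard).
    Returns both models and the analytically expected post-superposition
    RMSD, ``sigma * sqrt((3n - 6) / n)`` — the rigid fit absorbs six degrees
    of freedom.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_points, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.cumsum(3.8 * steps, axis=0)  # Cα-trace-like 3.8 Å steps

    if transform is None:
        R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        t = rng.uniform(-20, 20, size=3)
    else:
        R, t = np.asarray(transform[0]), np.asarray(transform[1])
    moved = coords @ R.T + t
    if mirror:
        moved = moved * np.array([-1.0, 1.0, 1.0])
    moved = moved + rng.normal(scale=noise_sigma, size=moved.shape)

    def as_model(name: str, xyz: np.ndarray) -> StructureModel:
        residues = [
            Residue(
                name="ALA",
                seqid=i + 1,
                atoms={"CA": Atom(name="CA", element="C", pos=xyz[i])},
            )
            for i in range(len(xyz))
        ]
        return StructureModel(name=name, chains={"A": residues})

    expected = noise_sigma * float(np.sqrt(max(3 * n_points - 6, 1) / n_points))
    return as_model("reference", coords), as_model("moved", moved), expected
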