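"""Crystal-structure comparison: superposition, deviations, distances, spines.

Operations mirror the structural quantities of the TK analysis: least-squares
rigid-body superposition (Kabsch/SVD with reflection guard) and its RMSD,
per-residue Cα deviations after superposition, functional-group distances
such as the K68–E83 open-conformation gap, and contiguity checks of the
catalytic and regulatory spines.

Coordinate files (PDB or mmCIF) are parsed through gemmi into a light
in-memory model keeping author numbering and insertion codes; for atoms with
alternate locations the highest-occupancy conformer is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .align import ScoringScheme, global_align  # noqa: F401 (scheme is API)

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "Correspondence",
    "SuperpositionResult",
    "FunctionalDistance",
    "SpineReport",
    "StructureFormatError",
    "DegenerateGeometryError",
    "read_structure",
    "write_pdb",
    "build_correspondence",
    "superpose",
    "superpose_models",
    "per_residue_deviation",
    "functional_group_distance",
    "spine_check",
    "sidechain_min_distance",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Terminal charged atoms of the "lateral group" distance rule.
TERMINAL_CHARGED_ATOMS = {
    "LYS": ("NZ",),
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}


class StructureFormatError(ValueError):
    """Unreadable or truncated coordinate file."""


class DegenerateGeometryError(ValueError):
    """Point set too degenerate (collinear / too few pairs) to superpose."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    name: str
    seqid: int           # author numbering
    icode: str = ""
    atoms: dict[str, Atom] = field(default_factory=dict)
    polymer: bool = True

    @property
    def key(self) -> tuple[int, str]:
        return (self.seqid, self.icode)

    def sidechain_atoms(self) -> list[Atom]:
        return [
            a
            for n, a in self.atoms.items()
            if n not in BACKBONE_ATOMS and a.element != "H"
        ]

    def one_letter(self) -> str:
        info = gemmi.find_tabulated_residue(self.name)
        if info and info.is_amino_acid():
            return info.one_letter_code.upper()
        return "X"


@dataclass
class StructureModel:
    """Chains of residues of one coordinate model."""

    name: str
    chains: dict[str, list[Residue]]

    def chain(self, chain_id: str) -> list[Residue]:
        return self.chains[chain_id]

    def polymer(self, chain_id: str) -> list[Residue]:
        return [r for r in self.chains[chain_id] if r.polymer]

    def residue(self, chain_id: str, seqid: int, icode: str = "") -> Residue:
        for r in self.chains[chain_id]:
            if r.seqid == seqid and r.icode == icode:
                return r
        raise KeyError(f"{chain_id}/{seqid}{icode}")

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter() for r in self.polymer(chain_id))

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains.values() for r in c)


def read_structure(path: str | Path) -> StructureModel:
    """Parse a PDB or mmCIF file (first model).

    Highest-occupancy alternate locations are kept; waters and
    small-molecule ligands are retained but flagged non-polymer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path.name} contains no models")
    st.setup_entities()
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            polymer = bool(info and info.is_amino_acid())
            atoms: dict[str, Atom] = {}
            for atom in res:
                cand = Atom(
                    name=atom.name,
                    element=atom.element.name,
                    pos=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    altloc=atom.altloc,
                )
                prev = atoms.get(atom.name)
                if prev is None or cand.occupancy > prev.occupancy:
                    atoms[atom.name] = cand
            residues.append(
                Residue(
                    name=res.name,
                    seqid=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    atoms=atoms,
                    polymer=polymer,
                )
            )
        chains[chain.name] = residues
    return StructureModel(name=st.name or path.stem, chains=chains)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model as a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.name
    md = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        ch = gemmi.Chain(chain_id)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.seqid, res.icode or " ")
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                ga.occ = atom.occupancy
                gr.add_atom(ga)
            ch.add_residue(gr)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass
class Correspondence:
    """One-to-one residue pairing restricted to a named atom (default Cα)."""

    pairs: list[tuple[tuple[str, int, str], tuple[str, int, str]]]
    atom_name: str = "CA"

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def coordinates(
        self, a: StructureModel, b: StructureModel
    ) -> tuple[np.ndarray, np.ndarray]:
        pa, pb = [], []
        for (ca, sa, ia), (cb, sb, ib) in self.pairs:
            ra = a.residue(ca, sa, ia)
            rb = b.residue(cb, sb, ib)
            pa.append(ra.atoms[self.atom_name].pos)
            pb.append(rb.atoms[self.atom_name].pos)
        return np.asarray(pa), np.asarray(pb)


def build_correspondence(
    a: StructureModel,
    b: StructureModel,
    chain_a: str,
    chain_b: str,
    atom_name: str = "CA",
    scheme: ScoringScheme | None = None,
) -> Correspondence:
    """Pair residues of two chains by sequence alignment.

    The chain one-letter sequences are globally aligned; aligned non-gap
    columns where both residues carry the named atom become pairs.  No
    outlier trimming is applied.
    """
    res_a = [r for r in a.polymer(chain_a) if atom_name in r.atoms]
    res_b = [r for r in b.polymer(chain_b) if atom_name in r.atoms]
    seq_a = "".join(r.one_letter() for r in res_a)
    seq_b = "".join(r.one_letter() for r in res_b)
    aln = global_align(seq_a, seq_b, scheme)
    pairs = []
    ia = ib = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            ra, rb = res_a[ia], res_b[ib]
            pairs.append(
                ((chain_a, ra.seqid, ra.icode), (chain_b, rb.seqid, rb.icode))
            )
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return Correspondence(pairs=pairs, atom_name=atom_name)


@dataclass
class SuperpositionResult:
    """Least-squares rigid-body superposition of paired points.

    ``rotation`` is orthonormal with det +1 (reflections disallowed);
    moving coordinates map onto the reference as ``rotation @ x + translation``.
    ``rmsd**2`` equals the mean of squared per-pair deviations exactly.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    per_pair_deviation: np.ndarray
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(moving: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal rigid-body fit of ``moving`` onto ``reference`` (Kabsch/SVD).

    Both arrays are (n, 3) with n >= 3 non-collinear points.  The SVD
    construction includes the reflection guard: det(U) is forced to +1, so
    mirrored inputs yield a proper rotation and a non-zero RMSD.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("expected matching (n, 3) coordinate arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise DegenerateGeometryError("collinear point set; rotation undetermined")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    dev = np.linalg.norm(moved - Q, axis=1)
    rmsd = float(np.sqrt(np.mean(dev**2)))
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd, per_pair_deviation=dev, n_pairs=n
    )


def superpose_models(
    a: StructureModel,
    b: StructureModel,
    chain_a: str,
    chain_b: str,
    corr: Correspondence | None = None,
    scheme: ScoringScheme | None = None,
) -> tuple[SuperpositionResult, Correspondence]:
    """Superpose chain_b of ``b`` onto chain_a of ``a``.

    The correspondence is built by sequence alignment when not supplied.
    """
    if corr is None:
        corr = build_correspondence(a, b, chain_a, chain_b, scheme=scheme)
    pa, pb = corr.coordinates(a, b)
    return superpose(pb, pa), corr


def per_residue_deviation(
    result: SuperpositionResult, corr: Correspondence
) -> list[tuple[tuple, tuple, float]]:
    """Post-superposition deviation (Å) per corresponding residue pair."""
    if len(corr.pairs) != result.n_pairs:
        raise ValueError("correspondence does not match the superposition")
    return [
        (pa, pb, float(d))
        for (pa, pb), d in zip(corr.pairs, result.per_pair_deviation)
    ]


@dataclass
class FunctionalDistance:
    """A functional-group distance per chain copy, aggregated across copies.

    ``spread`` is the half-range over chain copies.  Chains lacking the
    required side-chain atoms are listed in ``unresolved`` and excluded —
    never replaced by a fabricated distance.
    """

    per_chain: dict[str, float]
    mean: float | None
    spread: float | None
    rule: str
    unresolved: list[str] = field(default_factory=list)


def _terminal_atoms(res: Residue) -> list[Atom]:
    names = TERMINAL_CHARGED_ATOMS.get(res.name, ())
    return [res.atoms[n] for n in names if n in res.atoms]


def functional_group_distance(
    model: StructureModel,
    res_a: int | tuple[str, int],
    res_b: int | tuple[str, int],
    rule: str = "terminal-charged-atoms",
) -> FunctionalDistance:
    """Distance between the lateral groups of two residues, per chain copy.

    ``terminal-charged-atoms`` (default): minimum distance between the
    terminal charged atoms of the two residues (e.g. lysine NZ vs either
    glutamate carboxylate oxygen).  ``closest-heavy-sidechain``: minimum over
    all side-chain heavy-atom pairs.  Residue addresses are either an author
    seqid (evaluated in every chain containing both residues) or an explicit
    (chain, seqid) pair.
    """
    if rule not in ("terminal-charged-atoms", "closest-heavy-sidechain"):
        raise ValueError(f"unknown rule {rule!r}")

    def addr(spec, chain_id):
        if isinstance(spec, tuple):
            return spec
        return (chain_id, spec)

    chain_ids = (
        [res_a[0]]
        if isinstance(res_a, tuple)
        else sorted(model.chains)
    )
    per_chain: dict[str, float] = {}
    unresolved: list[str] = []
    for cid in chain_ids:
        ca, sa = addr(res_a, cid)
        cb, sb = addr(res_b, cid)
        try:
            ra = model.residue(ca, sa)
            rb = model.residue(cb, sb)
        except KeyError:
            unresolved.append(cid)
            continue
        if rule == "terminal-charged-atoms":
            atoms_a = _terminal_atoms(ra)
            atoms_b = _terminal_atoms(rb)
        else:
            atoms_a = ra.sidechain_atoms()
            atoms_b = rb.sidechain_atoms()
        if not atoms_a or not atoms_b:
            unresolved.append(cid)
            continue
        if ra is rb:
            per_chain[cid] = 0.0
            continue
        per_chain[cid] = min(
            float(np.linalg.norm(x.pos - y.pos)) for x in atoms_a for y in atoms_b
        )
    if per_chain:
        vals = np.array(list(per_chain.values()))
        mean = float(vals.mean())
        spread = float((vals.max() - vals.min()) / 2.0)
    else:
        mean = spread = None
    return FunctionalDistance(
        per_chain=per_chain, mean=mean, spread=spread, rule=rule,
        unresolved=unresolved,
    )


def sidechain_min_distance(
    model: StructureModel, a: tuple[str, int], b: tuple[str, int]
) -> float:
    """Minimum side-chain heavy-atom distance between two residues (Å)."""
    ra = model.residue(*a)
    rb = model.residue(*b)
    atoms_a = ra.sidechain_atoms() or list(ra.atoms.values())
    atoms_b = rb.sidechain_atoms() or list(rb.atoms.values())
    return min(
        float(np.linalg.norm(x.pos - y.pos)) for x in atoms_a for y in atoms_b
    )


@dataclass
class SpineReport:
    """Contiguity of a hydrophobic spine.

    ``links`` holds the minimum side-chain heavy-atom distance of each
    consecutive residue pair.  The spine is contiguous iff every link is
    within the cutoff; a missing residue leaves contiguity undefined.
    """

    links: list[tuple[int, int, float]]
    cutoff: float
    contiguous: bool | None
    failing: list[tuple[int, int]] = field(default_factory=list)
    missing: list[int] = field(default_factory=list)
    completion_contact: float | None = None


def spine_check(
    model: StructureModel,
    chain_id: str,
    residues: Sequence[int],
    cutoff: float = 5.5,
    completion_pair: tuple[int, int] | None = None,
) -> SpineReport:
    """Check contiguity of a spine given as ordered author seqids.

    ``completion_pair`` optionally reports one extra contact distance — e.g.
    the CRD −2 residue (A328) against the θ residue column (M66) that
    completes the catalytic spine.
    """
    missing = []
    for seqid in residues:
        try:
            model.residue(chain_id, seqid)
        except KeyError:
            missing.append(seqid)
    if missing:
        return SpineReport(
            links=[], cutoff=cutoff, contiguous=None, missing=missing
        )
    links = []
    failing = []
    for s1, s2 in zip(residues, residues[1:]):
        d = sidechain_min_distance(model, (chain_id, s1), (chain_id, s2))
        links.append((s1, s2, d))
        if d > cutoff:
            failing.append((s1, s2))
    completion = None
    if completion_pair is not None:
        try:
            completion = sidechain_min_distance(
                model, (chain_id, completion_pair[0]), (chain_id, completion_pair[1])
            )
        except KeyError:
            completion = None
    return SpineReport(
        links=links,
        cutoff=cutoff,
        contiguous=not failing,
        failing=failing,
        missing=[],
        completion_contact=completion,
    )
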