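"""Reading, labelling and curation of titin-kinase (TK) region sequence sets.

A TK-region record covers the N-terminal linker (NL), the kinase domain and
the C-terminal regulatory domain (CRD) — roughly 355 residues.  Records carry
optional biological labels (taxon class, fish clade, titin isoform) encoded as
``key=value`` tokens in the FASTA description, or supplied through a sidecar
TSV.  Curation removes keyword-flagged entries (e.g. myosin light chain
kinases, LOW_QUALITY annotations), exact duplicates, and partial sequences
that fail to cover the kinase-domain anchors of a reference annotation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "ALPHABET",
    "Labels",
    "SeqRecord",
    "SequenceSet",
    "CurationReport",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "read_labels_tsv",
    "curate",
]

#: The 20 standard amino acids plus the ambiguity code X.
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

TAXON_CLASSES = ("mammal", "fish", "other", "unknown")
FISH_CLADES = ("neoteleostei", "non-neoteleostei", "none", "unknown")
ISOFORMS = ("a", "b", "none", "unknown")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA entries (empty sequence, illegal residue)."""


@dataclass(frozen=True)
class Labels:
    """Biological labels of a TK-region sequence.

    ``unknown`` marks an unannotated field; ``none`` is a positive statement
    (e.g. a mammalian sequence has no fish clade).
    """

    taxon_class: str = "unknown"
    fish_clade: str = "unknown"
    isoform: str = "unknown"

    def __post_init__(self) -> None:
        if self.taxon_class not in TAXON_CLASSES:
            raise ValueError(f"unknown taxon_class {self.taxon_class!r}")
        if self.fish_clade not in FISH_CLADES:
            raise ValueError(f"unknown fish_clade {self.fish_clade!r}")
        if self.isoform not in ISOFORMS:
            raise ValueError(f"unknown isoform {self.isoform!r}")

    @property
    def known(self) -> bool:
        return "unknown" not in (self.taxon_class, self.fish_clade, self.isoform)

    @property
    def group(self) -> str:
        """Canonical 5-way group name: ``mammal`` or ``isoform/clade``."""
        if self.taxon_class == "mammal":
            return "mammal"
        if self.isoform in ("a", "b") and self.fish_clade in (
            "neoteleostei",
            "non-neoteleostei",
        ):
            return f"{self.isoform}/{self.fish_clade}"
        return "unknown"

    def get(self, key: str) -> str:
        if key == "group":
            return self.group
        return getattr(self, key)


@dataclass(frozen=True)
class SeqRecord:
    """One TK-region protein sequence.

    ``local_numbering_offset`` records the parent-protein position of residue
    1 of this record (e.g. 27887 for the medaka ttnb construct, whose first
    methionine is set as residue 1 in the local frame).
    """

    id: str
    residues: str
    description: str = ""
    labels: Labels = field(default_factory=Labels)
    local_numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {self.id!r} contains illegal residue(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based local position."""
        return self.residues[position - 1]


@dataclass
class SequenceSet:
    """An ordered collection of SeqRecords with provenance."""

    records: list[SeqRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SeqRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, rec_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def groups(self, key: str = "group") -> dict[str, list[SeqRecord]]:
        out: dict[str, list[SeqRecord]] = {}
        for r in self.records:
            out.setdefault(r.labels.get(key), []).append(r)
        return out


@dataclass
class CurationReport:
    """Tallies of the curation passes; counts always sum to ``n_input``."""

    n_input: int
    n_removed_keyword: int
    n_removed_duplicate: int
    n_removed_partial: int
    n_kept: int
    removed_ids: list[str] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (
            self.n_kept
            + self.n_removed_keyword
            + self.n_removed_duplicate
            + self.n_removed_partial
        )
        if total != self.n_input:
            raise ValueError("curation counts do not sum to n_input")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id", "reason"])
            for rid in self.removed_ids:
                w.writerow([rid, self.reasons[rid]])


_LABEL_KEYS = {
    "taxon_class": "taxon_class",
    "taxon": "taxon_class",
    "clade": "fish_clade",
    "fish_clade": "fish_clade",
    "isoform": "isoform",
}


def _labels_from_tokens(tokens: Iterable[str]) -> Labels:
    kv: dict[str, str] = {}
    for tok in tokens:
        if "=" not in tok:
            continue
        key, _, val = tok.partition("=")
        key = key.strip().lower()
        if key in _LABEL_KEYS:
            kv[_LABEL_KEYS[key]] = val.strip()
    return Labels(**kv) if kv else Labels()


def read_fasta(path: str | Path, labels: dict[str, Labels] | None = None) -> SequenceSet:
    """Read a FASTA file into a SequenceSet, order preserved.

    Headers are split into id (first token) and description; ``key=value``
    tokens in the description (isoform=, clade=, taxon_class=) populate the
    labels.  An explicit ``labels`` mapping (e.g. from :func:`read_labels_tsv`)
    overrides header-derived labels.

    Raises ``FileNotFoundError`` for a missing file and
    :class:`FastaFormatError` for an empty sequence or an illegal character,
    naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SeqRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        desc_tokens = entry.description.split()[1:]  # drop the id token
        description = " ".join(desc_tokens)
        lab = _labels_from_tokens(desc_tokens)
        if labels and entry.id in labels:
            lab = labels[entry.id]
        records.append(
            SeqRecord(
                id=entry.id,
                residues=str(entry.seq).upper(),
                description=description,
                labels=lab,
            )
        )
    return SequenceSet(records, provenance=f"read_fasta({path.name})")


def write_fasta(sset: SequenceSet, path: str | Path) -> None:
    """Write a SequenceSet as FASTA, encoding known labels as header tags."""
    with open(path, "w") as fh:
        for rec in sset:
            desc = rec.description
            if rec.labels != Labels() and "isoform=" not in desc:
                tags = (
                    f"taxon_class={rec.labels.taxon_class} "
                    f"clade={rec.labels.fish_clade} "
                    f"isoform={rec.labels.isoform}"
                )
                desc = f"{desc} {tags}".strip()
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def read_labels_tsv(path: str | Path) -> dict[str, Labels]:
    """Read a sidecar label table (columns: id, taxon_class, fish_clade, isoform)."""
    out: dict[str, Labels] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["id"]] = Labels(
                taxon_class=row.get("taxon_class", "unknown") or "unknown",
                fish_clade=row.get("fish_clade", "unknown") or "unknown",
                isoform=row.get("isoform", "unknown") or "unknown",
            )
    return out


def curate(
    sset: SequenceSet,
    exclude_keywords: Sequence[str] = (),
    reference=None,
    scheme=None,
) -> tuple[SequenceSet, CurationReport]:
    """Curate a sequence set with the three-pass filtering rule.

    Passes, in order:

    1. remove records whose description contains any excluded keyword
       (case-insensitive; e.g. "myosin light chain kinase", "LOW_QUALITY");
    2. remove exact duplicate residue strings, keeping the first occurrence;
    3. remove *partial* records: those whose column map onto ``reference``
       (a :class:`~titinkit.motifs.ReferenceAnnotation`) fails to cover every
       kinase-domain anchor column, or that cannot be mapped at all.

    Pass 3 runs only when ``reference`` is provided.  Returns the curated set
    and a :class:`CurationReport`; curation is idempotent.
    """
    if not sset.records:
        raise ValueError("cannot curate an empty sequence set")
    keywords = [k.lower() for k in exclude_keywords]

    kept: list[SeqRecord] = []
    removed: list[str] = []
    reasons: dict[str, str] = {}
    n_kw = 0
    for rec in sset:
        text = f"{rec.id} {rec.description}".lower()
        if any(k in text for k in keywords):
            n_kw += 1
            removed.append(rec.id)
            reasons[rec.id] = "keyword"
        else:
            kept.append(rec)

    seen: set[str] = set()
    unique: list[SeqRecord] = []
    n_dup = 0
    for rec in kept:
        if rec.residues in seen:
            n_dup += 1
            removed.append(rec.id)
            reasons[rec.id] = "duplicate"
        else:
            seen.add(rec.residues)
            unique.append(rec)

    n_partial = 0
    if reference is not None:
        from .motifs import UnmappableError, map_columns

        if not reference.kinase_anchor_positions():
            raise ValueError("reference annotation lacks kinase-domain anchors")
        full: list[SeqRecord] = []
        for rec in unique:
            try:
                cmap = map_columns(rec, reference, scheme)
                covered = cmap.covers(reference.kinase_anchor_names())
            except UnmappableError:
                covered = False
            if covered:
                full.append(rec)
            else:
                n_partial += 1
                removed.append(rec.id)
                reasons[rec.id] = "partial"
        unique = full

    report = CurationReport(
        n_input=len(sset),
        n_removed_keyword=n_kw,
        n_removed_duplicate=n_dup,
        n_removed_partial=n_partial,
        n_kept=len(unique),
        removed_ids=removed,
        reasons=reasons,
    )
    curated = SequenceSet(list(unique), provenance=sset.provenance + " | curated")
    return curated, report


def with_labels(rec: SeqRecord, **kwargs) -> SeqRecord:
    """Return a copy of ``rec`` with replaced label fields."""
    return replace(rec, labels=replace(rec.labels, **kwargs))
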