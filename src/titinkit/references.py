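"""Reference annotations for the TK region.

The default annotation frame is the medaka ttnb (medTKb) construct, in which
the parent-protein residue M27887 is local residue 1.  Anchor positions in
this frame: catalytic lysine K68, helix-αC glutamate E83, catalytic aspartate
D159, ELG slot 179–181, P+1 position A202, R-spine L87/L98/H157/L180, C-spine
V53/M66/I120/I165/V166/Y167/L224/L228, YD motif at 12–13 with contacts
E43/S116/R170, hinge acids D119/D122, and in the CRD the αR1 motif, the
R-7x-R arginines R330/R338 and the −2 position A328.

The real medTKb and human TK sequences are not bundled; the shipped
reference carries a *synthetic* backbone — random residues with the
canonical anchor residues implanted at the annotated positions — which is
sufficient for column mapping, motif extraction and all simulation-based
analyses.  Supply a real sequence via ``medtkb_annotation(sequence=...)`` to
anchor against the deposited construct.  For human TK (PDB 4JNW numbering)
only the paper-known anchor positions are tabulated.
"""

from __future__ import annotations

import numpy as np

from .motifs import ReferenceAnnotation
from .seq_io import Labels, SeqRecord

__all__ = [
    "MEDTKB_PARENT_OFFSET",
    "MEDTKB_ANCHORS",
    "HUMAN_TK_ANCHORS",
    "CANONICAL_RESIDUES",
    "synthetic_reference",
    "medtkb_annotation",
]

#: Parent-protein (NCBI XP_023806503) position of local residue 1.
MEDTKB_PARENT_OFFSET = 27887

#: Construct length of the NL + kinase + CRD region.
MEDTKB_LENGTH = 355

MEDTKB_ANCHORS: dict[str, tuple | int] = {
    "gly_rich_loop": (45, 46, 47, 48, 49, 50),
    "beta3_theta": 66,
    "beta3_lysine": 68,
    "alphaC_glutamate": 83,
    "catalytic_aspartate": 159,
    "dfg_slot": (179, 180, 181),
    "p_plus1": 202,
    "nl_window": (1, 33),
    "crd_window": (291, 355),
    "c_spine": (53, 66, 120, 165, 166, 167, 224, 228),
    "r_spine": (87, 98, 157, 180),
    "yd": (12, 13),
    "yd_contacts": (43, 116, 170),
    "r7xr_first": 330,
    "r7xr_second": 338,
    "minus2": 328,
    "hinge_acids": (119, 122),
}

#: Human TK anchor positions known in the PDB 4JNW numbering frame.
HUMAN_TK_ANCHORS: dict[str, int] = {
    "catalytic_aspartate": 144,
    "p_plus1_tyrosine": 187,
    "hrd_arginine": 146,
    "relay_glutamine": 167,
    "relay_arginine": 323,
    "regulatory_tyrosine": 170,
}

#: Canonical residue at each single-position anchor of the medTKb frame.
CANONICAL_RESIDUES: dict[int, str] = {
    11: "N",   # residue commonly preceding the YD motif
    12: "Y", 13: "D",                      # NL anchoring motif
    43: "E",                               # YD contact, strand β1
    45: "G", 46: "K", 47: "G", 48: "S", 49: "F", 50: "G",  # gly-rich loop
    53: "V",                               # C-spine
    66: "M", 67: "A", 68: "K",             # θxK (MAK in medTKb)
    83: "E",                               # helix αC glutamate
    87: "L", 98: "L",                      # R-spine
    116: "S",                              # hinge-loop YD contact
    119: "D", 120: "I", 122: "D",          # hinge acids + C-spine I120
    157: "H",                              # R-spine
    159: "D",                              # catalytic aspartate
    165: "I", 166: "V", 167: "Y",          # C-spine
    170: "R",                              # YD contact
    179: "E", 180: "L", 181: "G",          # ELG slot (canonical DFG)
    202: "A",                              # P+1 position (A in medTKb)
    224: "L", 228: "L",                    # C-spine
    300: "R", 301: "H", 302: "K", 303: "R", 304: "Y", 305: "Y",  # αR1 motif
    328: "A",                              # −2 position
    330: "R", 338: "R",                    # R-7x-R
}

# Random backbone fill avoids creating confounding motif hits: no Y in the
# NL window (spurious YD) and no R/H in the CRD window (spurious R-7x-R or
# αR1 matches).  Real TK sequences satisfy this by conservation.
_AA = "ACDEFGHIKLMNPQRSTVWY"
_NL_EXCLUDE = set("Y")
_CRD_EXCLUDE = set("RH")


def backbone_alphabet(position: int, anchors: dict = MEDTKB_ANCHORS) -> str:
    """Letters allowed as random background at a 1-based position."""
    nl = anchors["nl_window"]
    crd = anchors["crd_window"]
    if nl[0] <= position <= nl[1]:
        return "".join(c for c in _AA if c not in _NL_EXCLUDE)
    if crd[0] <= position <= crd[1]:
        return "".join(c for c in _AA if c not in _CRD_EXCLUDE)
    return _AA


def synthetic_reference(seed: int = 2025, length: int = MEDTKB_LENGTH) -> SeqRecord:
    """A synthetic medTKb-frame reference backbone.

    Random residues with the canonical anchor residues implanted at the
    annotated positions.  Deterministic under ``seed``.  This is a
    constructed stand-in for the deposited medTKb sequence, usable for
    column mapping and simulation; it is not the biological sequence.
    """
    rng = np.random.default_rng(seed)
    residues = [
        rng.choice(list(backbone_alphabet(p))) for p in range(1, length + 1)
    ]
    for pos, res in CANONICAL_RESIDUES.items():
        if pos <= length:
            residues[pos - 1] = res
    return SeqRecord(
        id="medTKb_synthetic",
        residues="".join(residues),
        description="synthetic medTKb-frame reference backbone "
        "(canonical anchor residues on a random background)",
        labels=Labels(taxon_class="fish", fish_clade="neoteleostei", isoform="b"),
        local_numbering_offset=MEDTKB_PARENT_OFFSET,
    )


def medtkb_annotation(
    sequence: SeqRecord | None = None, seed: int = 2025
) -> ReferenceAnnotation:
    """The medTKb reference annotation (default annotation of the package).

    With ``sequence=None`` the synthetic backbone from
    :func:`synthetic_reference` is used; pass the deposited construct
    sequence (NCBI XP_023806503 residues 27887–28241) to anchor against the
    real protein.
    """
    ref = sequence if sequence is not None else synthetic_reference(seed)
    return ReferenceAnnotation(reference=ref, **MEDTKB_ANCHORS)
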