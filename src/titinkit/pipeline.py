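"""End-to-end conveniences tying the pipeline stages together."""

from __future__ import annotations

from typing import Mapping

from .align import ScoringScheme
from .motifs import (
    MotifSignature,
    ReferenceAnnotation,
    UnmappableError,
    extract_signature,
    map_columns,
)
from .seq_io import Labels, SequenceSet
from .simmap import ClusterAssignment, Embedding, assign_and_classify, build_similarity, embed

__all__ = ["classify_families", "signatures_for_set"]


def classify_families(
    sset: SequenceSet,
    anchors: Mapping[str, Labels],
    k: int = 5,
    method: str = "nearest-centroid",
    scheme: ScoringScheme | None = None,
) -> tuple[ClusterAssignment, Embedding]:
    """Similarity map → embedding → anchor-oriented classification."""
    sim = build_similarity(sset, scheme)
    emb = embed(sim, k=k)
    assignment = assign_and_classify(emb, anchors, method=method)
    return assignment, emb


def signatures_for_set(
    sset: SequenceSet,
    ref: ReferenceAnnotation,
    scheme: ScoringScheme | None = None,
) -> list[MotifSignature]:
    """Motif signatures for every mappable sequence of a set."""
    out: list[MotifSignature] = []
    for rec in sset:
        try:
            cmap = map_columns(rec, ref, scheme)
        except UnmappableError:
            continue
        out.append(extract_signature(rec, cmap, ref))
    return out
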