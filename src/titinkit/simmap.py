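"""Pairwise-similarity map: correlation transform, spectral embedding and
isoform/clade classification.

Raw pairwise alignment scores s_ij are normalised into correlation-like
coefficients r_ij = s_ij / sqrt(s_ii * s_jj), giving a symmetric matrix with
unit diagonal.  A spectral embedding of r places each sequence as a vector
x_i from the origin such that dot products x_i . x_j approximate r_ij; the
dimensions are ordered by non-increasing eigenvalue, so earlier dimensions
carry the more prominent sequence divergences.  Cluster structure (titin
isoform a/b, fish clade, mammals) is read off the embedding with labelled
anchor sequences resolving the eigenvector sign ambiguity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .align import ScoringScheme, score_pair
from .seq_io import Labels, SequenceSet

__all__ = [
    "SimilarityMatrix",
    "Embedding",
    "ClusterAssignment",
    "AmbiguityError",
    "build_similarity",
    "embed",
    "assign_and_classify",
    "split_dimension",
]


class AmbiguityError(ValueError):
    """Anchors of the same label fall on opposite sides of a dimension."""


@dataclass
class SimilarityMatrix:
    """Raw scores s_ij and normalised coefficients r_ij for a sequence set."""

    ids: list[str]
    s: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.s.shape != (n, n) or self.r.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.s, self.s.T):
            raise ValueError("s must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("r must have unit diagonal")

    def reorder(self, order: Sequence[int]) -> "SimilarityMatrix":
        idx = np.asarray(order)
        return SimilarityMatrix(
            [self.ids[i] for i in idx],
            self.s[np.ix_(idx, idx)],
            self.r[np.ix_(idx, idx)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.ids, columns=self.ids)


def build_similarity(
    sset: SequenceSet | Sequence, scheme: ScoringScheme | None = None
) -> SimilarityMatrix:
    """Pairwise global-alignment scores and their correlation transform.

    r_ij = s_ij / sqrt(s_ii * s_jj); r_ii = 1 by construction.  Raises
    ``ValueError`` with fewer than 3 sequences or when any self-score is
    non-positive (the scheme is then unusable for normalisation).
    """
    records = list(sset)
    if len(records) < 3:
        raise ValueError("similarity map needs at least 3 sequences")
    n = len(records)
    s = np.zeros((n, n))
    for i in range(n):
        s[i, i] = score_pair(records[i], records[i], scheme)
    if np.any(np.diag(s) <= 0):
        raise ValueError("non-positive self-score; scheme unusable for normalisation")
    for i, j in itertools.combinations(range(n), 2):
        s[i, j] = s[j, i] = score_pair(records[i], records[j], scheme)
    d = np.sqrt(np.diag(s))
    r = s / np.outer(d, d)
    if np.any(r <= -1.0):
        raise ValueError("r_ij <= -1 encountered; scheme unusable for embedding")
    r = np.minimum(r, 1.0)  # guard float overshoot for (near-)identical pairs
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix([r.id for r in records], s, r)


def _fit_error(x: np.ndarray, r: np.ndarray) -> float:
    """Sum over i <= j of (x_i . x_j - r_ij)^2; the unit diagonal is part
    of the fitting objective, which makes the error non-increasing in k."""
    resid = x @ x.T - r
    iu = np.triu_indices_from(resid, k=0)
    return float(np.sum(resid[iu] ** 2))


@dataclass
class Embedding:
    """Per-sequence coordinate vectors with their eigenvalue spectrum.

    ``coordinates[i, d]`` is dimension d+1 of sequence i; dimensions are
    ordered by non-increasing eigenvalue.  ``reconstruction_error`` is
    sum_{i<=j} (x_i . x_j - r_ij)^2 — the unit diagonal is included in the
    fit, so the error is non-increasing in k.
    """

    ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    k: int
    reconstruction_error: float
    rank_deficient: bool = False

    def dim(self, d: int) -> np.ndarray:
        """Coordinates of (1-based) dimension ``d``."""
        return self.coordinates[:, d - 1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{d}" for d in range(1, self.k + 1)]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def embed(
    sim: SimilarityMatrix, k: int = 5, refine: bool = False
) -> Embedding:
    """Spectral embedding of the coefficient matrix r.

    Eigendecomposition of r; x_i(d) = sqrt(lambda_d) * v_d(i) for the top-k
    positive eigenvalues.  If fewer than k eigenvalues are positive, the
    achievable dimensions are returned with ``rank_deficient=True``.  Signs
    are fixed deterministically (largest-magnitude coordinate positive);
    anchors may re-orient them later.  With ``refine=True`` a least-squares
    polish of the same objective is run and kept only if it does not
    increase the reconstruction error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    r = sim.r
    if not np.allclose(r, r.T):
        raise ValueError("r must be symmetric")
    w, v = np.linalg.eigh(r)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    n_pos = int(np.sum(w > 1e-12))
    k_eff = min(k, n_pos)
    lam = w[:k_eff]
    x = v[:, :k_eff] * np.sqrt(lam)
    # deterministic sign: the largest-magnitude coordinate of each dimension
    # is positive
    for d in range(k_eff):
        i = int(np.argmax(np.abs(x[:, d])))
        if x[i, d] < 0:
            x[:, d] = -x[:, d]
    if refine:
        n = len(sim.ids)

        def objective(flat: np.ndarray) -> float:
            xm = flat.reshape(n, k_eff)
            resid = xm @ xm.T - r
            return float(np.sum(np.triu(resid) ** 2))

        res = optimize.minimize(objective, x.ravel(), method="L-BFGS-B")
        x_ref = res.x.reshape(n, k_eff)
        if _fit_error(x_ref, r) <= _fit_error(x, r):
            x = x_ref
    return Embedding(
        ids=list(sim.ids),
        coordinates=x,
        eigenvalues=lam,
        k=k_eff,
        reconstruction_error=_fit_error(x, r),
        rank_deficient=k_eff < k,
    )


@dataclass
class ClusterAssignment:
    """Cluster, isoform and clade calls for every sequence.

    ``table`` has one row per sequence: id, cluster, isoform, clade.
    ``signs`` records the axis orientation applied per dimension.
    """

    table: pd.DataFrame
    anchors: dict[str, Labels]
    signs: dict[int, float]
    method: str

    def call(self, rec_id: str) -> tuple[str, str, str]:
        row = self.table.loc[rec_id]
        return row["cluster"], row["isoform"], row["clade"]

    @property
    def clusters(self) -> dict[str, str]:
        return dict(self.table["cluster"])


def _labels_of(lab: Labels | Mapping[str, str]) -> Labels:
    if isinstance(lab, Labels):
        return lab
    return Labels(**{k: v for k, v in lab.items()})


def _cluster_name(lab: Labels) -> str:
    if lab.taxon_class == "mammal":
        return "mammal"
    return f"{lab.isoform}/{lab.fish_clade}"


def _calls_for_cluster(name: str) -> tuple[str, str]:
    """(isoform call, clade call) for a cluster name."""
    if name == "mammal":
        return "none", "mammal"
    iso, _, clade = name.partition("/")
    return iso, clade


def assign_and_classify(
    emb: Embedding,
    anchors: Mapping[str, Labels | Mapping[str, str]],
    method: str = "nearest-centroid",
    isoform_dim: int = 2,
    clade_dim: int = 3,
) -> ClusterAssignment:
    """Classify sequences into isoform/clade clusters using labelled anchors.

    ``anchors`` maps sequence ids (present in the embedding) to their known
    labels — e.g. the annotated zebrafish ttna/ttnb sequences.  Two methods:

    - ``"sign-quadrant"``: orient eigenvector signs so each anchor falls on
      its labelled side (isoform a / neoteleostei negative); isoform is then
      the sign of ``isoform_dim``, clade the sign of ``clade_dim``.  Raises
      :class:`AmbiguityError` if same-label anchors disagree in sign.
    - ``"nearest-centroid"`` (default; required when mammals are included):
      assign each sequence to the nearest anchor-defined centroid in
      dimensions 2..k.

    Anchor sequences always recover their own labels.
    """
    if not anchors:
        raise ValueError("at least one labelled anchor is required")
    missing = [a for a in anchors if a not in emb.ids]
    if missing:
        raise KeyError(f"anchor ids not in embedding: {missing}")
    anchor_labels = {a: _labels_of(lab) for a, lab in anchors.items()}
    idx = {rec_id: i for i, rec_id in enumerate(emb.ids)}
    x = emb.coordinates.copy()
    signs: dict[int, float] = {d: 1.0 for d in range(1, emb.k + 1)}

    if method == "sign-quadrant":
        # negative side: isoform a (dimension isoform_dim), neoteleostei
        # (dimension clade_dim) — matching the published axis convention
        for dim, key, negative in (
            (isoform_dim, "isoform", "a"),
            (clade_dim, "fish_clade", "neoteleostei"),
        ):
            if dim > emb.k:
                raise ValueError(f"dimension {dim} not available (k={emb.k})")
            wanted: list[float] = []
            for a, lab in anchor_labels.items():
                val = lab.get(key)
                if val in ("none", "unknown"):
                    continue
                coord = x[idx[a], dim - 1]
                if coord == 0:
                    continue
                desired = -1.0 if val == negative else 1.0
                wanted.append(desired * np.sign(coord))
            if wanted and len(set(wanted)) > 1:
                raise AmbiguityError(
                    f"dimension {dim} does not separate the anchor labels"
                )
            if wanted and wanted[0] < 0:
                x[:, dim - 1] = -x[:, dim - 1]
                signs[dim] = -1.0
        rows = []
        for rec_id in emb.ids:
            iso = "a" if x[idx[rec_id], isoform_dim - 1] < 0 else "b"
            clade = (
                "neoteleostei"
                if x[idx[rec_id], clade_dim - 1] < 0
                else "non-neoteleostei"
            )
            rows.append((rec_id, f"{iso}/{clade}", iso, clade))
    elif method == "nearest-centroid":
        if emb.k < 2:
            raise ValueError("nearest-centroid needs k >= 2")
        sub = x[:, 1:]  # dimensions 2..k
        centroids: dict[str, np.ndarray] = {}
        for name in sorted({_cluster_name(lab) for lab in anchor_labels.values()}):
            members = [
                idx[a] for a, lab in anchor_labels.items()
                if _cluster_name(lab) == name
            ]
            centroids[name] = sub[members].mean(axis=0)
        names = list(centroids)
        cmat = np.stack([centroids[n] for n in names])
        rows = []
        for rec_id in emb.ids:
            d2 = np.sum((cmat - sub[idx[rec_id]]) ** 2, axis=1)
            name = names[int(np.argmin(d2))]
            iso, clade = _calls_for_cluster(name)
            rows.append((rec_id, name, iso, clade))
    else:
        raise ValueError(f"unknown method {method!r}")

    table = pd.DataFrame(
        rows, columns=["id", "cluster", "isoform", "clade"]
    ).set_index("id", drop=False)
    # anchors must recover their own labels
    for a, lab in anchor_labels.items():
        expected = _cluster_name(lab)
        if method == "nearest-centroid" and table.loc[a, "cluster"] != expected:
            raise AmbiguityError(
                f"anchor {a!r} not assigned to its own cluster {expected!r}"
            )
    return ClusterAssignment(
        table=table, anchors=anchor_labels, signs=signs, method=method
    )


def split_dimension(emb: Embedding, labels: Mapping[str, str]) -> int:
    """The (1-based) dimension that best separates a binary labelling.

    ``labels`` maps a subset of sequence ids to one of exactly two values;
    the returned dimension maximises the absolute point-biserial correlation
    between its coordinates and the label indicator.  Used to verify that a
    deeper divergence (isoform) surfaces in an earlier dimension than a
    shallower one (clade).
    """
    values = sorted(set(labels.values()))
    if len(values) != 2:
        raise ValueError("labels must take exactly two values")
    ids = [i for i in emb.ids if i in labels]
    y = np.array([1.0 if labels[i] == values[1] else 0.0 for i in ids])
    rows = [emb.ids.index(i) for i in ids]
    best_dim, best = 1, -1.0
    for d in range(1, emb.k + 1):
        coord = emb.coordinates[rows, d - 1]
        if np.std(coord) == 0 or np.std(y) == 0:
            continue
        rho = abs(float(np.corrcoef(coord, y)[0, 1]))
        if rho > best:
            best, best_dim = rho, d
    return best_dim
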