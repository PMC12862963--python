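"""Similarity→correlation transform, spectral embedding and classification."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from titinkit import (
    AmbiguityError,
    SeqRecord,
    SequenceSet,
    assign_and_classify,
    build_similarity,
    embed,
    score_pair,
    split_dimension,
)
from titinkit.seq_io import Labels
from titinkit.simmap import SimilarityMatrix
from titinkit.synth import SimConfig, default_anchor_ids, simulate_families


def make_set(seqs):
    return SequenceSet(
        [SeqRecord(id=f"s{i}", residues=s) for i, s in enumerate(seqs)]
    )


class TestBuildSimilarity:
    def test_identical_sequences_give_all_ones(self, scheme):
        sim = build_similarity(make_set(["ACDEFGHIKL"] * 3), scheme)
        assert np.allclose(sim.r, 1.0)

    def test_normalisation_formula(self, scheme):
        sset = make_set(["ACDEFGHIKL", "ACDEFGHIKW", "WYKACDEFGH"])
        sim = build_similarity(sset, scheme)
        for i in range(3):
            for j in range(3):
                expected = sim.s[i, j] / np.sqrt(sim.s[i, i] * sim.s[j, j])
                assert sim.r[i, j] == pytest.approx(min(expected, 1.0))

    def test_matches_independent_scores(self, scheme, rng):
        """r recomputed element-wise from independently computed scores."""
        AA = "ACDEFGHIKLMNPQRSTVWY"
        seqs = ["".join(rng.choice(list(AA), 25)) for _ in range(5)]
        sim = build_similarity(make_set(seqs), scheme)
        for i in range(5):
            for j in range(5):
                s_ij = score_pair(seqs[i], seqs[j], scheme)
                s_ii = score_pair(seqs[i], seqs[i], scheme)
                s_jj = score_pair(seqs[j], seqs[j], scheme)
                assert sim.r[i, j] == pytest.approx(
                    min(s_ij / np.sqrt(s_ii * s_jj), 1.0)
                )

    def test_needs_three_sequences(self, scheme):
        with pytest.raises(ValueError):
            build_similarity(make_set(["ACD", "ACE"]), scheme)

    def test_symmetric_with_unit_diagonal(self, small_family, scheme):
        sset, _ = small_family
        sim = build_similarity(SequenceSet(sset.records[:8]), scheme)
        assert np.allclose(sim.r, sim.r.T)
        assert np.allclose(np.diag(sim.r), 1.0)
        assert np.all(sim.r <= 1.0)


def block_matrix(n_per_block=3, within=0.9, between=0.6):
    n = 2 * n_per_block
    r = np.full((n, n), between)
    r[:n_per_block, :n_per_block] = within
    r[n_per_block:, n_per_block:] = within
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix([f"s{i}" for i in range(n)], r.copy(), r)


class TestEmbed:
    def test_rank_one_matrix(self):
        r = np.ones((4, 4))
        sim = SimilarityMatrix(list("abcd"), r.copy(), r.copy())
        emb = embed(sim, k=3)
        assert emb.eigenvalues[0] == pytest.approx(4.0)
        assert np.allclose(emb.dim(1), emb.dim(1)[0])
        if emb.k > 1:
            assert np.allclose(emb.coordinates[:, 1:], 0.0, atol=1e-9)

    def test_two_block_matrix_separates_by_sign(self):
        emb = embed(block_matrix(), k=3)
        signs = np.sign(emb.dim(2))
        assert len(set(signs[:3])) == 1
        assert len(set(signs[3:])) == 1
        assert signs[0] != signs[3]

    def test_dot_products_reproduce_rank_k_matrix(self, rng):
        """Exact recovery: for rank-k r with unit diagonal, embedded dot
        products reproduce r within 1e-6."""
        k = 3
        v = rng.normal(size=(8, k))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        # bias all vectors into a half-space so off-diagonals stay > -1
        v[:, 0] = np.abs(v[:, 0]) + 0.5
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = v @ v.T
        sim = SimilarityMatrix([f"s{i}" for i in range(8)], r.copy(), r.copy())
        emb = embed(sim, k=k)
        recon = emb.coordinates @ emb.coordinates.T
        assert np.max(np.abs(recon - r)) < 1e-6

    def test_reconstruction_error_monotone_in_k(self, small_family, scheme):
        sset, _ = small_family
        sim = build_similarity(SequenceSet(sset.records[:10]), scheme)
        errors = [embed(sim, k=k).reconstruction_error for k in (1, 2, 3, 4, 5)]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))

    def test_eigenvalues_non_increasing(self, small_family, scheme):
        sset, _ = small_family
        sim = build_similarity(SequenceSet(sset.records[:10]), scheme)
        emb = embed(sim, k=4)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-12)

    def test_rank_deficiency_flagged(self):
        r = np.ones((4, 4))
        sim = SimilarityMatrix(list("abcd"), r.copy(), r.copy())
        emb = embed(sim, k=3)
        assert emb.rank_deficient
        assert emb.k < 3

    def test_refinement_never_increases_error(self, small_family, scheme):
        sset, _ = small_family
        sim = build_similarity(SequenceSet(sset.records[:8]), scheme)
        plain = embed(sim, k=3, refine=False)
        refined = embed(sim, k=3, refine=True)
        assert refined.reconstruction_error <= plain.reconstruction_error + 1e-12


@pytest.fixture(scope="module")
def family():
    cfg = SimConfig(seed=11, n_per_group=6)
    sset, truth = simulate_families(cfg)
    sim = build_similarity(sset)
    return sset, truth, embed(sim, k=4)


class TestAssignAndClassify:
    def test_nearest_centroid_recovers_truth(self, family):
        sset, truth, emb = family
        asn = assign_and_classify(emb, default_anchor_ids(truth))
        true = [truth.groups[i] for i in emb.ids]
        pred = [asn.clusters[i] for i in emb.ids]
        assert adjusted_rand_score(true, pred) == 1.0

    def test_anchors_recover_own_labels(self, family):
        sset, truth, emb = family
        anchors = default_anchor_ids(truth)
        asn = assign_and_classify(emb, anchors)
        for a, lab in anchors.items():
            cluster, iso, clade = asn.call(a)
            assert iso == lab.isoform or lab.taxon_class == "mammal"

    def test_sign_quadrant_on_fish_only(self):
        cfg = SimConfig(seed=13, n_per_group=6)
        sset, truth = simulate_families(cfg)
        fish = SequenceSet([r for r in sset if r.labels.taxon_class == "fish"])
        emb = embed(build_similarity(fish), k=4)
        iso_dim = split_dimension(
            emb, {r.id: r.labels.isoform for r in fish}
        )
        clade_dim = split_dimension(
            emb, {r.id: r.labels.fish_clade for r in fish}
        )
        anchors = {
            r.id: r.labels
            for r in [fish.records[0], fish.records[6], fish.records[12],
                      fish.records[18]]
        }
        asn = assign_and_classify(
            emb, anchors, method="sign-quadrant",
            isoform_dim=iso_dim, clade_dim=clade_dim,
        )
        for r in fish:
            cluster, iso, clade = asn.call(r.id)
            assert iso == r.labels.isoform
            assert clade == r.labels.fish_clade

    def test_single_cluster_gets_anchor_label(self):
        cfg = SimConfig(seed=5, n_per_group={"b/neoteleostei": 6})
        sset, truth = simulate_families(cfg)
        emb = embed(build_similarity(sset), k=2)
        anchors = {sset.records[0].id: sset.records[0].labels}
        asn = assign_and_classify(emb, anchors, method="nearest-centroid")
        assert set(asn.table["cluster"]) == {"b/neoteleostei"}

    def test_conflicting_anchors_raise(self, family):
        sset, truth, emb = family
        # two anchors labelled isoform a that sit on opposite sides of the
        # isoform dimension: fake by giving a b-group sequence an 'a' label
        a_id = truth.per_sequence.iloc[
            truth.per_sequence["group"].tolist().index("a/neoteleostei")
        ]["id"]
        b_id = truth.per_sequence.iloc[
            truth.per_sequence["group"].tolist().index("b/neoteleostei")
        ]["id"]
        fish_iso = {
            r.id: r.labels.isoform
            for r in sset if r.labels.taxon_class == "fish"
        }
        iso_dim = split_dimension(emb, fish_iso)
        anchors = {
            a_id: Labels("fish", "neoteleostei", "a"),
            b_id: Labels("fish", "neoteleostei", "a"),  # mislabelled
        }
        with pytest.raises(AmbiguityError):
            assign_and_classify(
                emb, anchors, method="sign-quadrant",
                isoform_dim=iso_dim, clade_dim=min(iso_dim + 1, emb.k),
            )

    def test_order_invariance(self, family):
        sset, truth, emb = family
        sim = build_similarity(sset)
        anchors = default_anchor_ids(truth)
        asn1 = assign_and_classify(embed(sim, k=4), anchors)
        order = np.random.default_rng(0).permutation(len(sim.ids))
        sim2 = sim.reorder(order)
        asn2 = assign_and_classify(embed(sim2, k=4), anchors)
        for rec_id in sim.ids:
            assert asn1.clusters[rec_id] == asn2.clusters[rec_id]


class TestHierarchicalOrdering:
    def test_isoform_split_in_earlier_dimension_than_clade(self):
        """The deeper isoform divergence surfaces before the clade split."""
        cfg = SimConfig(seed=23, n_per_group=6)
        sset, truth = simulate_families(cfg)
        fish = SequenceSet([r for r in sset if r.labels.taxon_class == "fish"])
        emb = embed(build_similarity(fish), k=4)
        iso_dim = split_dimension(emb, {r.id: r.labels.isoform for r in fish})
        clade_dim = split_dimension(
            emb, {r.id: r.labels.fish_clade for r in fish}
        )
        assert iso_dim < clade_dim
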