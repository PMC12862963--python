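"""Coordinate parsing, Kabsch superposition, distances and spine checks."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from titinkit import (
    DegenerateGeometryError,
    build_correspondence,
    functional_group_distance,
    per_residue_deviation,
    read_structure,
    spine_check,
    superpose,
    superpose_models,
    write_pdb,
)
from titinkit.structure import Atom, Residue, StructureModel
from titinkit.synth import simulate_structure_pair

from _oracles import numeric_superposition_rmsd

MINIMAL_PDB = """\
ATOM      1  N   ALA A  10      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A  10      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  CB  ALA A  10      12.919   6.898  -5.041  1.00 10.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40 10.00           C
END
"""


def residue(seqid, name, atoms):
    return Residue(
        name=name,
        seqid=seqid,
        atoms={n: Atom(name=n, element=n[0], pos=np.asarray(p)) for n, p in atoms.items()},
    )


def ca_model(coords, name="m"):
    residues = [
        residue(i + 1, "ALA", {"CA": c}) for i, c in enumerate(np.asarray(coords))
    ]
    return StructureModel(name=name, chains={"A": residues})


class TestReadStructure:
    def test_minimal_file_coordinates_exact(self, tmp_path):
        p = tmp_path / "min.pdb"
        p.write_text(MINIMAL_PDB)
        model = read_structure(p)
        res = model.residue("A", 10)
        assert res.name == "ALA"
        assert model.n_atoms() == 3
        assert np.array_equal(res.atoms["CA"].pos, [11.639, 6.071, -5.147])

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        model = read_structure(p)
        res = model.residue("A", 1)
        assert len(res.atoms) == 1
        assert res.atoms["CA"].pos[0] == 1.000  # the 0.6 conformer

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "none.pdb")

    def test_write_read_roundtrip(self, tmp_path):
        a, _, _ = simulate_structure_pair(seed=4, n_points=20, noise_sigma=0.0)
        p = tmp_path / "out.pdb"
        write_pdb(a, p)
        back = read_structure(p)
        pa = np.array([r.atoms["CA"].pos for r in a.polymer("A")])
        pb = np.array([r.atoms["CA"].pos for r in back.polymer("A")])
        assert np.allclose(pa, pb, atol=1e-3)  # PDB format: 3 decimals


class TestSuperpose:
    def test_identical_selections(self, rng):
        pts = rng.normal(size=(10, 3))
        res = superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(res.translation, 0.0, atol=1e-12)

    def test_rigid_transform_recovered(self, rng):
        pts = rng.normal(size=(25, 3)) * 10
        R = Rotation.random(random_state=1).as_matrix()
        t = np.array([3.0, -7.0, 11.0])
        moved = pts @ R.T + t
        res = superpose(moved, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation @ R, np.eye(3), atol=1e-9)

    def test_rotation_is_proper_orthonormal(self, rng):
        pts = rng.normal(size=(12, 3))
        noisy = pts + rng.normal(scale=0.3, size=pts.shape)
        res = superpose(noisy, pts)
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_mirrored_input_keeps_det_plus_one(self, rng):
        pts = rng.normal(size=(30, 3)) * 5
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        res = superpose(mirrored, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
        assert res.rmsd > 0.5

    def test_rmsd_squared_is_mean_squared_deviation(self, rng):
        pts = rng.normal(size=(15, 3))
        noisy = pts + rng.normal(scale=0.4, size=pts.shape)
        res = superpose(noisy, pts)
        assert res.rmsd**2 == pytest.approx(
            float(np.mean(res.per_pair_deviation**2))
        )

    def test_never_worse_than_unsuperposed(self, rng):
        pts = rng.normal(size=(20, 3)) * 8
        other = rng.normal(size=(20, 3)) * 8
        res = superpose(other, pts)
        raw = float(np.sqrt(np.mean(np.sum((other - pts) ** 2, axis=1))))
        assert res.rmsd <= raw + 1e-9

    def test_matches_numeric_optimizer(self, rng):
        """Kabsch solution equals direct numerical RMSD minimisation,
        including the 4-points-tight one-displaced configuration."""
        base = rng.normal(size=(5, 3)) * 4
        displaced = base.copy()
        displaced[2] += np.array([1.0, 0.0, 0.0])
        cases = [
            (displaced, base),
            (rng.normal(size=(8, 3)), rng.normal(size=(8, 3))),
        ]
        for moving, reference in cases:
            ours = superpose(moving, reference).rmsd
            oracle = numeric_superposition_rmsd(moving, reference)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_matches_scipy_align_vectors(self, rng):
        pts = rng.normal(size=(40, 3)) * 6
        noisy = pts + rng.normal(scale=0.5, size=pts.shape)
        ours = superpose(noisy, pts)
        rot, rssd = Rotation.align_vectors(
            pts - pts.mean(axis=0), noisy - noisy.mean(axis=0)
        )
        assert ours.rmsd == pytest.approx(rssd / np.sqrt(len(pts)), rel=1e-6)

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line + 1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPerResidueDeviation:
    def test_identical_structures_all_zero(self, rng):
        pts = rng.normal(size=(10, 3))
        a = ca_model(pts, "a")
        b = ca_model(pts, "b")
        res, corr = superpose_models(a, b, "A", "A")
        devs = per_residue_deviation(res, corr)
        assert all(d == pytest.approx(0.0, abs=1e-9) for _, _, d in devs)

    def test_single_displaced_residue(self, rng):
        pts = rng.normal(size=(30, 3)) * 10
        moved = pts.copy()
        # displace one residue; superposition of the other 29 dominates
        moved[7] += np.array([0.0, 0.0, 3.0])
        a = ca_model(pts, "a")
        b = ca_model(moved, "b")
        res, corr = superpose_models(a, b, "A", "A")
        devs = np.array([d for _, _, d in per_residue_deviation(res, corr)])
        assert np.argmax(devs) == 7
        assert np.sum(devs > 1.0) == 1

    def test_mean_square_reproduces_rmsd(self, rng):
        a, b, _ = simulate_structure_pair(seed=2, n_points=50, noise_sigma=0.5)
        res, corr = superpose_models(a, b, "A", "A")
        devs = np.array([d for _, _, d in per_residue_deviation(res, corr)])
        assert float(np.mean(devs**2)) == pytest.approx(res.rmsd**2)

    def test_gaussian_noise_mean_matches_chi_expectation(self):
        """With isotropic noise σ, per-pair deviations follow a chi(3)
        scaled by σ; the sample mean must sit within 3 standard errors."""
        sigma = 0.5
        a, b, _ = simulate_structure_pair(seed=9, n_points=100, noise_sigma=sigma)
        res, corr = superpose_models(a, b, "A", "A")
        devs = res.per_pair_deviation
        chi_mean = sigma * np.sqrt(2 / np.pi) * 2  # E|chi_3| = 2σ sqrt(2/π)
        chi_sd = sigma * np.sqrt(3 - 8 / np.pi)
        se = chi_sd / np.sqrt(len(devs))
        assert abs(float(np.mean(devs)) - chi_mean) < 3 * se + 0.05


K68_E83_MODEL = StructureModel(
    name="toy",
    chains={
        "A": [
            residue(68, "LYS", {
                "N": (0, 0, 0), "CA": (1.5, 0, 0), "CB": (2, 1, 0),
                "NZ": (5, 2, 0),
            }),
            residue(83, "GLU", {
                "N": (8, 0, 0), "CA": (9, 0, 0), "CB": (9, 1, 0),
                "OE1": (5, 7, 0), "OE2": (9, 4, 0),
            }),
        ],
        "B": [
            residue(68, "LYS", {"CA": (0, 0, 0), "NZ": (0, 0, 0)}),
            residue(83, "GLU", {"CA": (3, 0, 0), "OE1": (0, 5.3, 0)}),
        ],
    },
)


class TestFunctionalGroupDistance:
    def test_same_residue_is_zero(self):
        d = functional_group_distance(K68_E83_MODEL, ("A", 68), ("A", 68))
        assert d.per_chain["A"] == 0.0

    def test_constructed_distance(self):
        """Chain A: NZ at (5,2,0); nearer carboxylate oxygen OE2 at (9,4,0)
        -> 2*sqrt(5); chain B: NZ to OE1 = 5.3 by construction."""
        d = functional_group_distance(K68_E83_MODEL, 68, 83)
        assert d.per_chain["A"] == pytest.approx(2 * np.sqrt(5))
        assert d.per_chain["B"] == pytest.approx(5.3)
        expected_mean = (2 * np.sqrt(5) + 5.3) / 2
        assert d.mean == pytest.approx(expected_mean)
        assert d.spread == pytest.approx(abs(2 * np.sqrt(5) - 5.3) / 2)

    def test_missing_sidechain_flagged_not_fabricated(self):
        model = StructureModel(
            name="nosc",
            chains={"A": [
                residue(68, "LYS", {"CA": (0, 0, 0)}),
                residue(83, "GLU", {"CA": (3, 0, 0), "OE1": (1, 1, 0)}),
            ]},
        )
        d = functional_group_distance(model, 68, 83)
        assert d.unresolved == ["A"]
        assert d.mean is None

    def test_closest_heavy_sidechain_rule(self):
        d = functional_group_distance(
            K68_E83_MODEL, ("A", 68), ("A", 83), rule="closest-heavy-sidechain"
        )
        # closest heavy side-chain pair is LYS NZ (5,2,0) to GLU CB (9,1,0)
        assert d.per_chain["A"] == pytest.approx(np.sqrt(17))


class TestSpineCheck:
    def make_line_model(self, spacing):
        residues = [
            residue(i + 1, "LEU", {"CA": (i * spacing, 0, 0),
                                    "CD1": (i * spacing, 1, 0)})
            for i in range(3)
        ]
        return StructureModel(name="line", chains={"A": residues})

    def test_contiguous_on_4A_line(self):
        report = spine_check(self.make_line_model(4.0), "A", [1, 2, 3])
        assert report.contiguous is True
        assert all(d == pytest.approx(4.0) for _, _, d in report.links)

    def test_broken_spine_identifies_failing_pair(self):
        model = self.make_line_model(4.0)
        far = residue(3, "LEU", {"CA": (28, 0, 0), "CD1": (28, 1, 0)})
        model.chains["A"][2] = far
        report = spine_check(model, "A", [1, 2, 3])
        assert report.contiguous is False
        assert report.failing == [(2, 3)]

    def test_missing_residue_leaves_contiguity_undefined(self):
        report = spine_check(self.make_line_model(4.0), "A", [1, 2, 9])
        assert report.contiguous is None
        assert report.missing == [9]

    def test_completion_contact_reported(self):
        report = spine_check(
            self.make_line_model(4.0), "A", [1, 2], completion_pair=(1, 3)
        )
        assert report.completion_contact == pytest.approx(8.0)


class TestCorrespondence:
    def test_sequence_alignment_pairs_residues(self, rng):
        pts = rng.normal(size=(20, 3)) * 10
        a = ca_model(pts, "a")
        # b misses the first three residues (like a shorter construct)
        b = StructureModel(
            name="b",
            chains={"A": [
                residue(100 + i, "ALA", {"CA": pts[i]}) for i in range(3, 20)
            ]},
        )
        corr = build_correspondence(a, b, "A", "A")
        assert corr.n_pairs == 17
        res, _ = superpose_models(a, b, "A", "A", corr=corr)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
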