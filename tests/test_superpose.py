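"""Kabsch superposition, outlier rejection and structure-based alignment."""

import numpy as np
import pytest

import calmscape as cs
from helpers import planted_outlier_check, quaternion_rmsd, quaternion_rotation


def cloud_pair(rng, n, rotate=True, noise=0.0):
    A = rng.normal(scale=10.0, size=(n, 3))
    if rotate:
        R = quaternion_rotation(rng.normal(size=(4, 3)),
                                rng.normal(size=(4, 3)))  # any proper rotation
    else:
        R = np.eye(3)
    t = rng.normal(scale=5.0, size=3)
    B = A @ R.T + t + rng.normal(scale=noise, size=(n, 3))
    return A, B


def full_corr(n):
    return cs.AtomCorrespondence(pairs=[(i, i) for i in range(n)],
                                 selection="CA-only")


class TestKabsch:
    def test_identical_coordinates(self, rng):
        A = rng.normal(size=(10, 3))
        res = cs.kabsch(full_corr(10), A, A)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_exact_rigid_transform_recovered(self, rng):
        A = rng.normal(scale=8.0, size=(12, 3))
        theta = np.pi / 2
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        t = np.array([1.0, 2.0, 3.0])
        B = A @ R.T + t
        res = cs.kabsch(full_corr(12), A, B)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(res.transform(B), A, atol=1e-8)
        np.testing.assert_allclose(res.rotation @ R, np.eye(3), atol=1e-8)

    def test_perturbed_point_matches_quaternion_oracle(self, rng):
        A = rng.normal(scale=5.0, size=(4, 3))
        B = A.copy()
        B[2] += np.array([1.0, 0.0, 0.0])
        res = cs.kabsch(full_corr(4), A, B)
        assert res.rmsd == pytest.approx(quaternion_rmsd(A, B), abs=1e-8)

    def test_proper_rotation_even_for_reflected_input(self, rng):
        A = rng.normal(size=(10, 3))
        B = A * np.array([-1.0, 1.0, 1.0])  # mirror image
        res = cs.kabsch(full_corr(10), A, B)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_too_few_pairs_rejected(self, rng):
        A = rng.normal(size=(2, 3))
        with pytest.raises(cs.SuperpositionError, match="3"):
            cs.kabsch(full_corr(2), A, A)

    def test_collinear_geometry_rejected(self):
        A = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(cs.SuperpositionError, match="degenerate"):
            cs.kabsch(full_corr(4), A, A)

    def test_oracle_agreement_on_random_instances(self, rng):
        # dual-route check: SVD construction vs quaternion eigenproblem
        for _ in range(200):
            n = int(rng.integers(4, 51))
            A, B = cloud_pair(rng, n, noise=float(rng.uniform(0, 2.0)))
            res = cs.kabsch(full_corr(n), A, B)
            assert res.rmsd == pytest.approx(quaternion_rmsd(A, B), abs=1e-8)

    def test_symmetry_forward_and_reverse(self, rng):
        A, B = cloud_pair(rng, 20, noise=0.5)
        fwd = cs.kabsch(full_corr(20), A, B)
        rev = cs.kabsch(full_corr(20), B, A)
        assert fwd.rmsd == pytest.approx(rev.rmsd, abs=1e-8)
        np.testing.assert_allclose(fwd.rotation @ rev.rotation, np.eye(3),
                                   atol=1e-8)

    def test_invariance_under_common_rigid_motion(self, rng):
        A, B = cloud_pair(rng, 15, noise=0.3)
        res = cs.kabsch(full_corr(15), A, B)
        theta = 0.7
        R = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        shift = np.array([3.0, -2.0, 8.0])
        res2 = cs.kabsch(full_corr(15), A @ R.T + shift, B @ R.T + shift)
        assert res2.rmsd == pytest.approx(res.rmsd, abs=1e-8)


class TestIterativeSuperpose:
    def test_clean_pair_single_cycle_equals_kabsch(self, backbone_pair):
        a, b, _ = backbone_pair
        corr, ca, cb = cs.correspondence_from_residues(a, b, "A", "A")
        plain = cs.kabsch(corr, ca, cb)
        iterated = cs.iterative_superpose(corr, ca, cb)
        assert iterated.cycles_run == 1
        assert iterated.rmsd == pytest.approx(plain.rmsd, abs=1e-10)
        assert iterated.n_retained == plain.n_retained

    def test_infinite_reject_factor_never_rejects(self, rng):
        A, B = cloud_pair(rng, 25, noise=1.0)
        corr = full_corr(25)
        plain = cs.kabsch(corr, A, B)
        res = cs.iterative_superpose(corr, A, B, reject_factor=np.inf)
        assert res.n_retained == 25
        assert res.rmsd == pytest.approx(plain.rmsd, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_outliers_rejected_exactly(self, seed):
        exact, rejected, truth = planted_outlier_check(seed)
        assert exact, f"rejected {rejected}, expected {truth}"

    def test_rmsd_non_increasing_and_below_initial(self):
        spec = cs.StructurePairSpec(
            n_residues=40, rotation_angle=0.8, rotation_axis=(1.0, 1.0, 0.0),
            translation=(2.0, 0.0, -4.0), noise_sd=0.1, n_outliers=3,
            outlier_displacement=10.0, seed=3)
        a, b, _ = cs.generate_structure_pair(spec)
        corr, ca, cb = cs.correspondence_from_residues(a, b, "A", "A")
        initial = cs.kabsch(corr, ca, cb)
        rmsds = []
        for cycles in (1, 2, 3, 4, 5):
            res = cs.iterative_superpose(corr, ca, cb, max_cycles=cycles,
                                         reject_unit="residue")
            rmsds.append(res.rmsd)
        assert all(r2 <= r1 + 1e-12 for r1, r2 in zip(rmsds, rmsds[1:]))
        assert rmsds[-1] <= initial.rmsd

    def test_residue_rejection_requires_groups(self, rng):
        A, B = cloud_pair(rng, 10)
        with pytest.raises(cs.SuperpositionError, match="group"):
            cs.iterative_superpose(
                cs.AtomCorrespondence(pairs=[(i, i) for i in range(10)],
                                      groups=None),
                A, B, reject_unit="residue")


class TestStructureBasedAlignment:
    def test_identical_chains_gapless_self_alignment(self, backbone_pair):
        a, b, _ = backbone_pair
        corr, ca, cb = cs.correspondence_from_residues(a, b, "A", "A")
        res = cs.kabsch(corr, ca, cb)
        row_a, row_b = cs.structure_based_alignment(a, b, res, "A", "A")
        assert row_a == row_b
        assert "-" not in row_a
        assert len(row_a) == 30

    def test_n_terminal_deletion_gives_leading_gaps(self):
        a, _, _ = cs.generate_structure_pair(
            cs.StructurePairSpec(n_residues=20, seed=13))
        trimmed = cs.StructureModel(a.atoms[a.atoms.res_id > 3])
        identity = cs.SuperpositionResult(
            rotation=np.eye(3), translation=np.zeros(3), rmsd=0.0,
            n_retained=0)
        row_a, row_b = cs.structure_based_alignment(a, trimmed, identity,
                                                    "A", "A")
        assert row_b.startswith("---")
        assert row_b[3:] == row_a[3:]
        seq_a, _ = a.one_letter_sequence("A")
        assert row_a == seq_a

    def test_zero_cutoff_gives_empty_alignment_with_warning(self,
                                                            backbone_pair):
        a, b, _ = backbone_pair
        corr, ca, cb = cs.correspondence_from_residues(a, b, "A", "A")
        res = cs.kabsch(corr, ca, cb)
        with pytest.warns(UserWarning, match="empty"):
            row_a, row_b = cs.structure_based_alignment(a, b, res, "A", "A",
                                                        pair_cutoff=0.0)
        assert row_a == "" and row_b == ""
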