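"""Kabsch fitting and the iterative outlier-rejection protocol."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from grinmap.fixtures import ToyStructureSpec, helix_coords, make_structure_pair
from grinmap.superposition import iterative_superpose, kabsch, rmsd

from _oracles import brute_force_min_rmsd


def random_rotation(seed):
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


class TestRmsd:
    def test_identical_lists_give_zero(self):
        P = helix_coords(10)
        assert rmsd(P, P) == 0.0

    def test_single_pair_distance(self):
        assert rmsd([[0, 0, 0]], [[0, 3, 0]]) == pytest.approx(3.0)

    def test_two_pairs_rms_of_distances(self):
        # distances 1 and 7: sqrt((1 + 49)/2) = 5
        P = [[0, 0, 0], [10, 0, 0]]
        Q = [[1, 0, 0], [17, 0, 0]]
        assert rmsd(P, Q) == pytest.approx(5.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestKabsch:
    def test_identity_on_equal_clouds(self):
        P = helix_coords(4)
        sup = kabsch(P, P)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_known_rotation(self, seed):
        P = helix_coords(12)
        R = random_rotation(seed)
        t = np.array([1.0, -2.0, 3.0])
        Q = P @ R.T + t
        sup = kabsch(P, Q)
        assert sup.rmsd <= 1e-9
        assert np.allclose(sup.rotation, R, atol=1e-6)
        assert np.allclose(sup.translation, t, atol=1e-6)

    def test_optimal_vs_brute_force_on_displaced_cloud(self):
        # 4-point cloud, one point displaced 1 Å along z
        P = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        Q = P.copy()
        Q[3, 2] += 1.0
        sup = kabsch(P, Q)
        oracle = brute_force_min_rmsd(P, Q)
        assert sup.rmsd == pytest.approx(oracle, abs=1e-3)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_optimal_vs_brute_force_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(-5, 5, size=(6, 3))
        Q = rng.uniform(-5, 5, size=(6, 3))
        sup = kabsch(P, Q)
        assert sup.rmsd == pytest.approx(brute_force_min_rmsd(P, Q), abs=1e-3)

    @pytest.mark.parametrize("seed", [5, 6, 7, 8])
    def test_rmsd_invariant_under_common_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(20, 3))
        Q = rng.normal(size=(20, 3))
        base = kabsch(P, Q).rmsd
        R = random_rotation(seed + 100)
        t = rng.uniform(-10, 10, 3)
        moved = kabsch(P @ R.T + t, Q @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("seed", [9, 10, 11])
    def test_fitted_rmsd_never_exceeds_unfitted(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(15, 3))
        Q = rng.normal(size=(15, 3))
        assert kabsch(P, Q).rmsd <= rmsd(P, Q) + 1e-12

    def test_proper_rotation_for_reflected_input(self):
        P = helix_coords(8)
        Q = P.copy()
        Q[:, 2] *= -1  # mirror image
        sup = kabsch(P, Q)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError):
            kabsch(P, P)

    @pytest.mark.parametrize("sigma", [0.1, 0.3])
    def test_rotation_recovery_under_noise(self, sigma):
        """Recovered rotation within 2 degrees of truth at noise sigma <= 0.3 Å."""
        chain_a, chain_b, truth, tf = make_structure_pair(
            ToyStructureSpec(n_residues=50, noise_sigma=sigma, seed=13)
        )
        P = chain_a.coords(chain_a.positions)
        Q = chain_b.coords(chain_b.positions)
        sup = kabsch(P, Q)
        delta = sup.rotation @ tf["rotation"].T
        angle = np.rad2deg(np.arccos(np.clip((np.trace(delta) - 1) / 2, -1, 1)))
        assert angle < 2.0


class TestIterativeSuperpose:
    def test_identical_chains_need_no_rejection(self):
        chain_a, chain_b, truth, _ = make_structure_pair(
            ToyStructureSpec(n_residues=12, noise_sigma=0.0, seed=1)
        )
        sup = iterative_superpose(chain_a, chain_b, truth)
        assert sup.cycles_run == 0
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert len(sup.retained_pairs) == 12

    def test_displaced_residue_is_rejected(self):
        chain_a, chain_b, truth, _ = make_structure_pair(
            ToyStructureSpec(
                n_residues=12,
                noise_sigma=0.0,
                displaced_positions=((5, (6.0, 0.0, 0.0)),),
                seed=2,
            )
        )
        sup = iterative_superpose(chain_a, chain_b, truth, cycles=5, reject_cutoff=2.0)
        retained_a = {a for a, _ in sup.retained_pairs}
        assert retained_a == set(range(1, 13)) - {5}
        assert sup.rmsd < 0.1
        assert sup.rmsd_all > sup.rmsd

    def test_rmsd_non_increasing_over_cycles(self):
        chain_a, chain_b, truth, _ = make_structure_pair(
            ToyStructureSpec(n_residues=40, noise_sigma=0.8, seed=3)
        )
        rmsds = []
        for cycles in range(0, 6):
            sup = iterative_superpose(chain_a, chain_b, truth, cycles=cycles, reject_cutoff=1.2)
            rmsds.append(sup.rmsd)
        assert all(b <= a + 1e-9 for a, b in zip(rmsds, rmsds[1:]))

    def test_insufficient_seed_raises(self):
        chain_a, chain_b, truth, _ = make_structure_pair(
            ToyStructureSpec(n_residues=4, noise_sigma=0.0, seed=4)
        )
        # strip coordinates from all but two residues of B: < 3 usable pairs
        from grinmap.structures import ChainModel, ResidueSite

        sparse = ChainModel(
            chain_b.subunit,
            [
                ResidueSite(r.subunit, r.pos, r.aa, r.ca if r.pos <= 2 else None)
                for r in chain_b.residues
            ],
            chain_b.source,
        )
        with pytest.raises(ValueError, match="pairs"):
            iterative_superpose(chain_a, sparse, truth)

    def test_annealed_rejection_keeps_at_least_three_pairs(self):
        # every pair is beyond the cutoff, yet rejection floors at 3 pairs
        chain_a, chain_b, truth, _ = make_structure_pair(
            ToyStructureSpec(n_residues=10, noise_sigma=3.0, seed=5)
        )
        sup = iterative_superpose(chain_a, chain_b, truth, cycles=20, reject_cutoff=0.01)
        assert len(sup.retained_pairs) >= 3
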