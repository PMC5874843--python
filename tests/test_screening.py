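"""Orientation sampling, ensemble screening, and inclusion classification."""

import numpy as np
import pytest

from gelforge.energy import EnergyModel, LJCoulombModel
from gelforge.screening import (CavityFrame, Pose, cavity_frame_from_host,
                                classify_inclusion, rank_candidates,
                                sample_orientations, screen)
from gelforge.structures import Molecule
from gelforge.synthetic import make_rod_guest, make_toy_host, ToyHostSpec


class ZeroModel(EnergyModel):
    def total_energy(self, molecules):
        return 0.0


class TestSampleOrientations:
    def test_empty_and_determinism(self, toy_host, rod_guest):
        host, _ = toy_host
        rod, _ = rod_guest
        assert sample_orientations(host, rod, 0, seed=3) == []
        a = sample_orientations(host, rod, 50, seed=3)
        b = sample_orientations(host, rod, 50, seed=3)
        for p, q in zip(a, b):
            assert np.array_equal(p.rotation, q.rotation)
            assert np.array_equal(p.translation, q.translation)

    def test_invalid_shell(self, toy_host, rod_guest):
        with pytest.raises(ValueError):
            sample_orientations(toy_host[0], rod_guest[0], 5, shell=(5.0, 2.0))

    def test_rotations_uniform_mean_trace(self, toy_host, rod_guest):
        """E[tr R] = 0 for uniform rotations; Monte-Carlo check at 3 SE.

        tr R = 1 + 2 cos θ with rotation-angle density (1 − cos θ)/π on
        [0, π], so E[cos θ] = −1/2 and the mean trace vanishes.
        """
        poses = sample_orientations(toy_host[0], rod_guest[0], 10_000, seed=17)
        traces = np.array([np.trace(p.matrix()) for p in poses])
        se = traces.std(ddof=1) / np.sqrt(len(traces))
        assert abs(traces.mean() - 0.0) < 3 * se

    def test_translations_within_shell(self, toy_host, rod_guest):
        poses = sample_orientations(toy_host[0], rod_guest[0], 2000,
                                    shell=(2.0, 9.0), seed=5)
        r = np.array([np.linalg.norm(p.translation) for p in poses])
        assert r.min() >= 2.0 and r.max() <= 9.0

    def test_quaternion_normalization_enforced(self):
        with pytest.raises(ValueError):
            Pose(np.array([1.0, 0.5, 0, 0]), np.zeros(3))


class TestScreen:
    def test_constant_zero_model(self, toy_host, rod_guest):
        res = screen(toy_host[0], rod_guest[0], ZeroModel(), n=20, k=5, seed=1)
        assert res.mean == 0.0 and res.se == 0.0
        assert len(res.lowest_indices) == 5

    def test_k_equals_n_returns_all_sorted(self, toy_host, rod_guest, lj_model):
        res = screen(toy_host[0], rod_guest[0], lj_model, n=5, k=5, seed=2)
        e = res.lowest_energies
        assert len(e) == 5 and np.all(np.diff(e) >= 0)
        assert sorted(res.lowest_indices) == sorted(range(5))

    def test_ties_broken_by_pose_index(self, toy_host, rod_guest):
        res = screen(toy_host[0], rod_guest[0], ZeroModel(), n=10, k=4, seed=0)
        assert list(res.lowest_indices) == [0, 1, 2, 3]

    def test_n_less_than_k_rejected(self, toy_host, rod_guest, lj_model):
        with pytest.raises(ValueError):
            screen(toy_host[0], rod_guest[0], lj_model, n=3, k=5, seed=0)

    def test_se_halves_when_n_doubles(self, toy_host, rod_guest, lj_model):
        """SE ∝ 1/sqrt(n) on a clash-free shell (stochastic tolerance)."""
        host, frame = toy_host
        rod, _ = rod_guest
        shell = (12.0, 25.0)  # clash-free: finite-variance energies
        se_n = screen(host, rod, lj_model, n=4000, k=0, seed=3, shell=shell).se
        se_2n = screen(host, rod, lj_model, n=16000, k=0, seed=4, shell=shell).se
        assert se_2n == pytest.approx(se_n / 2.0, rel=0.3)


class TestCavityBasin:
    def test_lowest_poses_fall_in_cavity(self, toy_host, rod_guest, lj_model):
        """The screened low-energy poses concentrate in the ring cavity."""
        host, frame = toy_host
        rod, _ = rod_guest
        res = screen(host, rod, lj_model, n=20_000, k=100, seed=7)
        centroids = np.array([p.translation for p in res.lowest_poses])
        dist = np.linalg.norm(centroids - frame.center, axis=1)
        assert np.all(dist <= 1.5 * frame.rim_radius)

    def test_grid_search_confirms_global_basin(self, toy_host, lj_model):
        """Exhaustive translation grid: the global minimum basin is the cavity."""
        host, frame = toy_host
        rod, _ = make_rod_guest(4.0, 5)
        sig, eps, q = lj_model.atom_params(host)
        gs, ge, gq = lj_model.atom_params(rod)
        n_side = 100  # 10^6 grid points
        ax = np.linspace(-12, 12, n_side)
        rod_rel = rod.positions - rod.centroid()
        energies = np.empty((n_side, n_side, n_side))
        for iz, z in enumerate(ax):
            grid = np.stack(np.meshgrid(ax, ax, [z], indexing="ij"),
                            axis=-1).reshape(-1, 1, 3)
            pts = grid + rod_rel[None, :, :]
            em = lj_model.pair_energy_matrix(host.positions, sig, eps, q,
                                             pts, gs, ge, gq)
            energies[:, :, iz] = em.sum(axis=(-1, -2)).reshape(n_side, n_side)
        emin = energies.min()
        # every grid point within 50% of the minimum depth lies in the cavity
        basin = np.argwhere(energies <= 0.5 * emin)
        coords = np.column_stack([ax[basin[:, 0]], ax[basin[:, 1]],
                                  ax[basin[:, 2]]])
        dist = np.linalg.norm(coords - frame.center, axis=1)
        assert emin < 0
        assert np.all(dist <= 1.5 * frame.rim_radius)


class TestClassifyInclusion:
    def _posed(self, depth_a, depth_b):
        # two-ended guest: marker A at depth_a, marker B at depth_b on the axis
        pos = np.array([[0, 0, depth_a], [0, 0, (depth_a + depth_b) / 2],
                        [0, 0, depth_b]])
        return Molecule(["X", "X", "X"], pos)

    def test_outside_is_none(self, toy_host):
        _, frame = toy_host
        far = Molecule(["X", "X"], [[30.0, 0, 0], [32.0, 0, 0]])
        assert classify_inclusion(frame, far, ([0], [1])) == "none"

    def test_constructed_depths(self, toy_host):
        _, frame = toy_host
        guest = self._posed(2.0, -3.0)
        assert classify_inclusion(frame, guest, ([0], [2])) == "A"

    def test_mirror_flips_label(self, toy_host):
        _, frame = toy_host
        guest = self._posed(-2.0, 3.0)  # mirror through the rim plane
        assert classify_inclusion(frame, guest, ([0], [2])) == "B"

    def test_invariant_under_joint_rigid_motion(self, toy_host, rng):
        _, frame = toy_host
        guest = self._posed(2.0, -3.0)
        from scipy.spatial.transform import Rotation as R
        for _ in range(5):
            rot = R.random(rng=rng).as_matrix()
            t = rng.uniform(-20, 20, 3)
            g2 = guest.transformed(rotation=rot, translation=t)
            f2 = CavityFrame(rot @ frame.center + t, rot @ frame.axis,
                             frame.rim_radius)
            assert classify_inclusion(f2, g2, ([0], [2])) == "A"

    def test_marker_validation(self, toy_host):
        _, frame = toy_host
        guest = self._posed(1.0, -1.0)
        with pytest.raises(ValueError):
            classify_inclusion(frame, guest, ([], [2]))
        with pytest.raises(ValueError):
            classify_inclusion(frame, guest, ([0, 1], [1, 2]))

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            CavityFrame(np.zeros(3), np.zeros(3), 5.0)

    def test_frame_from_tagged_host(self):
        from gelforge.network import make_gamma_cyclodextrin
        cd, _ = make_gamma_cyclodextrin(0)
        frame = cavity_frame_from_host(cd)
        # construction: glycosidic O at midpoints of a 45°-spaced circle of
        # radius 6 → ring radius 6·cos(π/8); axis ±z with primary face +z
        assert frame.rim_radius == pytest.approx(6.0 * np.cos(np.pi / 8),
                                                 abs=1e-6)
        assert abs(frame.axis[2]) == pytest.approx(1.0, abs=1e-6)
        assert frame.axis[2] > 0  # secondary face at negative depth


class TestRankCandidates:
    def test_repulsive_augmentation_ranks_worse(self, toy_host, lj_model):
        """Adding a purely repulsive (like-charged) site must worsen the rank.

        Oracle: with shared poses the augmented candidate's ΔE exceeds the
        plain one's pose by pose, so its mean must be strictly higher.
        """
        host, _ = toy_host
        host = host.copy()
        host.charges = np.full(len(host), 0.1)
        rod, _ = make_rod_guest(4.0, 5)
        aug = Molecule(rod.elements + ["X"],
                       np.vstack([rod.positions, [[0, 0, 0.5]]]),
                       charges=list(rod.charges) + [1.0])
        model = LJCoulombModel()
        table = rank_candidates([("plain", rod), ("augmented", aug)], host,
                                model, n=2000, seed=4, shell=(12.0, 25.0))
        assert list(table["hydrogel"])[0] == "plain"
        assert table["mean_delta_e"].iloc[0] < table["mean_delta_e"].iloc[1]

    def test_single_candidate_rank_one(self, toy_host, rod_guest, lj_model):
        table = rank_candidates([("only", rod_guest[0])], toy_host[0],
                                lj_model, n=100, seed=1)
        assert list(table["id"]) == [1]

    def test_identical_candidates_identical_means(self, toy_host, rod_guest,
                                                  lj_model):
        rod, _ = rod_guest
        table = rank_candidates([("a", rod), ("b", rod)], toy_host[0],
                                lj_model, n=500, seed=2)
        assert table["mean_delta_e"].iloc[0] == table["mean_delta_e"].iloc[1]

    def test_empty_candidates_rejected(self, toy_host, lj_model):
        with pytest.raises(ValueError):
            rank_candidates([], toy_host[0], lj_model, n=10, seed=0)
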