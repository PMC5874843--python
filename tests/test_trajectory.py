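"""Frame observables: RGYR, SASA, water/capture counting, hydrogen bonds."""

import numpy as np
import pytest

from gelforge.trajectory import (Frame, ObservableSeries, Trajectory,
                                 block_average, count_captured_guests,
                                 count_hbonds, count_waters_in_gel,
                                 fibonacci_sphere, radius_of_gyration, sasa,
                                 series)


def _frame(coords, tags, masses=None, radii=None, elements=None, time=0.0):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return Frame(coords, tags,
                 np.ones(n) if masses is None else np.asarray(masses, float),
                 time=time,
                 radii=None if radii is None else np.asarray(radii, float),
                 elements=elements)


class TestRgyr:
    def test_single_atom_zero(self):
        f = _frame([[1.0, 2.0, 3.0]], ["gel"])
        assert radius_of_gyration(f, [0]) == 0.0

    def test_symmetric_dumbbell(self):
        f = _frame([[5.0, 0, 0], [-5.0, 0, 0]], ["gel", "gel"])
        assert radius_of_gyration(f, [0, 1]) == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self, rng):
        coords = rng.uniform(-10, 10, (100, 3))
        masses = rng.uniform(1, 16, 100)
        f = _frame(coords, ["gel"] * 100, masses=masses)
        com = (masses[:, None] * coords).sum(0) / masses.sum()
        expected = np.sqrt(sum(m * np.dot(r - com, r - com)
                               for m, r in zip(masses, coords)) / masses.sum())
        assert radius_of_gyration(f, range(100)) == pytest.approx(
            expected, abs=1e-10)

    def test_empty_selection_rejected(self):
        f = _frame([[0, 0, 0]], ["gel"])
        with pytest.raises(ValueError):
            radius_of_gyration(f, [])

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation as R
        coords = rng.uniform(-5, 5, (40, 3))
        masses = rng.uniform(1, 12, 40)
        f = _frame(coords, ["gel"] * 40, masses=masses)
        v0 = radius_of_gyration(f, range(40))
        rot = R.random(rng=rng).as_matrix()
        f2 = _frame(coords @ rot.T + rng.uniform(-30, 30, 3), ["gel"] * 40,
                    masses=masses)
        assert radius_of_gyration(f2, range(40)) == pytest.approx(v0, abs=1e-9)


class TestSasa:
    def test_single_sphere_analytic(self):
        f = _frame([[0, 0, 0]], ["gel"], radii=[1.9])
        expected = 4 * np.pi * (1.9 + 1.4) ** 2
        assert sasa(f, [0]) == pytest.approx(expected, rel=1e-12)

    def test_disjoint_spheres_additive(self):
        f = _frame([[0, 0, 0], [100.0, 0, 0]], ["gel", "gel"],
                   radii=[1.9, 1.9])
        expected = 2 * 4 * np.pi * 3.3 ** 2
        assert sasa(f, [0, 1]) == pytest.approx(expected, rel=1e-12)

    def test_overlapping_pair_vs_monte_carlo_oracle(self):
        """Two overlapping inflated spheres vs a dense random-point oracle."""
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        f = _frame(coords, ["gel", "gel"], radii=[1.9, 1.9])
        estimate = sasa(f, [0, 1], probe=1.4, n_points=960)
        rng = np.random.default_rng(1234)
        R = 3.3
        total = 0.0
        for a in range(2):
            pts = rng.normal(size=(1_000_000, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = coords[a] + R * pts
            other = coords[1 - a]
            exposed = np.linalg.norm(pts - other, axis=1) >= R
            total += exposed.mean() * 4 * np.pi * R ** 2
        assert estimate == pytest.approx(total, rel=0.01)

    def test_point_count_convergence(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        f = _frame(coords, ["gel", "gel"], radii=[1.9, 1.9])
        a = sasa(f, [0, 1], n_points=960)
        b = sasa(f, [0, 1], n_points=1920)
        assert abs(a - b) / b < 0.005

    def test_missing_radii_error_names_element(self):
        f = _frame([[0, 0, 0]], ["gel"], elements=["Qq"])
        with pytest.raises(ValueError, match="Qq"):
            sasa(f, [0])

    def test_fibonacci_points_unit_norm(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert len(np.unique(np.round(pts, 9), axis=0)) == 960


class TestWaterCount:
    def test_shell_criterion(self):
        # water O 2.9 Å from an isolated small gel cluster, outside envelope
        gel = [[0.0, 0, 0], [2.0, 0, 0]]
        f = _frame(gel + [[0, 2.9, 0]], ["gel", "gel", "water"],
                   radii=[1.7, 1.7, 1.52], elements=["C", "C", "O"])
        assert count_waters_in_gel(f) == 1

    def test_far_water_not_counted(self):
        gel = [[0.0, 0, 0], [2.0, 0, 0]]
        f = _frame(gel + [[50.0, 0, 0]], ["gel", "gel", "water"],
                   radii=[1.7, 1.7, 1.52], elements=["C", "C", "O"])
        assert count_waters_in_gel(f) == 0

    def test_hollow_shell_interior_ground_truth(self):
        """Waters sealed inside a hollow gel shell count; far ones do not."""
        shell = 10.0 * fibonacci_sphere(400)
        inside = 3.0 * fibonacci_sphere(7)
        outside = 40.0 * fibonacci_sphere(5)
        coords = np.vstack([shell, inside, outside])
        tags = ["gel"] * 400 + ["water"] * 12
        radii = np.concatenate([np.full(400, 1.7), np.full(12, 1.52)])
        f = _frame(coords, tags, radii=radii,
                   elements=["C"] * 400 + ["O"] * 12)
        assert count_waters_in_gel(f) == 7

    def test_monotone_in_shell_distance(self):
        shell = 10.0 * fibonacci_sphere(400)
        waters = np.array([[0, 0, 13.5], [0, 0, 16.0], [0, 0, 30.0]])
        coords = np.vstack([shell, waters])
        tags = ["gel"] * 400 + ["water"] * 3
        radii = np.concatenate([np.full(400, 1.7), np.full(3, 1.52)])
        f = _frame(coords, tags, radii=radii, elements=["C"] * 400 + ["O"] * 3)
        counts = [count_waters_in_gel(f, shell=s) for s in (2.0, 4.0, 7.0, 21.0)]
        assert counts == sorted(counts)

    def test_no_gel_rejected(self):
        f = _frame([[0, 0, 0]], ["water"], radii=[1.52], elements=["O"])
        with pytest.raises(ValueError):
            count_waters_in_gel(f)


class TestCapture:
    def _gel_and_guest(self, approach):
        gel = [[0.0, 0, 0]]
        guest = [[approach, 0, 0], [approach + 2.0, 0, 0]]
        return _frame(gel + guest, ["gel", "guest_0", "guest_0"])

    def test_threshold_bracket(self):
        assert count_captured_guests(self._gel_and_guest(4.4)) == 1
        assert count_captured_guests(self._gel_and_guest(4.6)) == 0

    def test_no_guests_zero(self):
        f = _frame([[0, 0, 0]], ["gel"])
        assert count_captured_guests(f) == 0

    def test_constructed_dozen(self):
        gel = 10.0 * fibonacci_sphere(100)
        pts, tags = [gel], ["gel"] * 100
        for i in range(12):
            u = gel[i] / np.linalg.norm(gel[i])
            pts.append((10.0 + 3.0) * u[None, :])
            tags.append(f"guest_{i}")
        for i in range(12, 30):
            u = gel[i] / np.linalg.norm(gel[i])
            pts.append((10.0 + 25.0) * u[None, :])
            tags.append(f"guest_{i}")
        f = _frame(np.vstack(pts), tags)
        assert count_captured_guests(f) == 12

    def test_monotone_in_contact(self):
        f = self._gel_and_guest(4.4)
        counts = [count_captured_guests(f, contact=c) for c in (1.0, 4.5, 10.0)]
        assert counts == sorted(counts)

    def test_persistence_non_increasing(self):
        # guest in contact on frames 0, 1, 3 only
        frames = []
        for k, approach in enumerate([4.0, 4.0, 20.0, 4.0]):
            f = self._gel_and_guest(approach)
            frames.append(Frame(f.coordinates, f.identities, f.masses,
                                time=float(k)))
        traj = Trajectory(frames)
        c1 = count_captured_guests(traj, persistence=1)
        c2 = count_captured_guests(traj, persistence=2)
        c3 = count_captured_guests(traj, persistence=3)
        assert list(c1) == [1, 1, 0, 1]
        assert list(c2) == [0, 1, 0, 0]
        assert list(c3) == [0, 0, 0, 0]
        assert np.all(c2 <= c1) and np.all(c3 <= c2)


class TestHbonds:
    def _linear(self, d_da, angle_deg):
        # donor O, its H along +x, acceptor placed at distance d_da from D
        # such that the D-H...A angle at H equals angle_deg
        d = np.array([0.0, 0, 0])
        h = np.array([0.96, 0, 0])
        ang = np.radians(180.0 - angle_deg)
        a = h + (d_da - 0.96) * np.array([np.cos(ang), np.sin(ang), 0])
        return _frame([d, h, a], ["gel", "gel", "guest_0"])

    def test_ideal_linear_counts(self):
        f = self._linear(2.8, 180.0)
        assert count_hbonds(f, donors=[(0, 1)], acceptors=[2]) == 1

    def test_bent_pair_rejected(self):
        f = self._linear(2.8, 90.0)
        assert count_hbonds(f, donors=[(0, 1)], acceptors=[2]) == 0

    def test_same_component_excluded(self):
        f = self._linear(2.8, 180.0)
        f2 = Frame(f.coordinates, ["gel", "gel", "gel"], f.masses)
        assert count_hbonds(f2, donors=[(0, 1)], acceptors=[2]) == 0

    def test_lattice_matches_brute_force(self, rng):
        """k geometrically valid bonds on a constructed lattice."""
        donors, acceptors, coords, tags = [], [], [], []
        k_true = 0
        for i in range(12):
            base = np.array([6.0 * i, 0, 0])
            coords += [base, base + [0.96, 0, 0]]
            tags += ["gel", "gel"]
            d_idx = 2 * i + len(acceptors)
            valid = i % 3 != 0  # every third pair is bent out of criterion
            if valid:
                a = base + [2.8, 0, 0]
                k_true += 1
            else:
                a = base + [0.96, 1.9, 0]
            coords.append(a)
            tags.append("guest_0")
        f = _frame(np.vstack(coords), tags)
        donors = [(3 * i, 3 * i + 1) for i in range(12)]
        acceptors = [3 * i + 2 for i in range(12)]
        assert count_hbonds(f, donors, acceptors) == k_true

    def test_missing_hydrogen_rejected(self):
        f = self._linear(2.8, 180.0)
        with pytest.raises(ValueError):
            count_hbonds(f, donors=[(0, None)], acceptors=[2])


class TestSeries:
    def _traj(self, values):
        frames = [Frame(np.array([[v, 0, 0], [-v, 0, 0]]), ["gel", "gel"],
                        np.ones(2), time=float(k))
                  for k, v in enumerate(values)]
        return Trajectory(frames)

    def test_constant_series_zero_se(self):
        s = series(self._traj([2.0] * 8), "rgyr")
        mean, se = block_average(s, 4)
        assert mean == pytest.approx(2.0)
        assert se == 0.0

    def test_one_block_plain_mean(self):
        s = series(self._traj([1.0, 2.0, 3.0]), "rgyr")
        mean, se = block_average(s, 1)
        assert mean == pytest.approx(2.0)
        assert se == 0.0

    def test_two_blocks_hand_computed(self):
        s = ObservableSeries(np.arange(4.0), np.array([1.0, 3.0, 1.0, 3.0]))
        mean, se = block_average(s, 2)
        # blocks (1,3) and (1,3): means 2 and 2
        assert mean == pytest.approx(2.0)
        assert se == 0.0
        s2 = ObservableSeries(np.arange(4.0), np.array([1.0, 1.0, 3.0, 3.0]))
        mean2, se2 = block_average(s2, 2)
        assert mean2 == pytest.approx(2.0)
        assert se2 == pytest.approx(np.std([1.0, 3.0], ddof=1) / np.sqrt(2))

    def test_unknown_observable_rejected(self):
        with pytest.raises(ValueError):
            series(self._traj([1.0]), "entropy")

    def test_remainder_joins_last_block(self):
        s = ObservableSeries(np.arange(5.0), np.array([1, 1, 1, 4, 4.0]))
        mean, _ = block_average(s, 2)
        # blocks: [1, 1] and [1, 4, 4] → means 1 and 3
        assert mean == pytest.approx(2.0)

    def test_times_strictly_increasing_enforced(self):
        f = Frame(np.zeros((1, 3)), ["gel"], np.ones(1), time=0.0)
        with pytest.raises(ValueError):
            Trajectory([f, f])
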