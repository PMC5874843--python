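"""Crosslinked-network construction: stoichiometry, bridges, grafting, guests."""

import numpy as np
import pytest

from gelforge.energy import LJCoulombModel
from gelforge.errors import (CapacityError, CrosslinkShortfallError,
                             PlacementError)
from gelforge.network import (BuilderConfig, build_matrix,
                              graft_cyclodextrins, local_relax,
                              make_gamma_cyclodextrin, place_guests,
                              target_crosslink_count)
from gelforge.structures import Molecule, build_pva_chain, molar_mass
from gelforge.synthetic import make_guest_stub

WATER = molar_mass("H2O")
SA = molar_mass("C4H6O4")

SMALL = dict(n_chains=8, chain_length=8, box_lengths=(34.0, 34.0, 30.0),
             pva_sa_ratio=(10, 1), relax_steps=5, n_guests=0)


class TestTargetCount:
    @pytest.mark.parametrize("n,ratio,expected", [
        (1960, (10, 2), 392),
        (100, (10, 2), 20),
        (0, (10, 2), 0),
        (35, (10, 2), 7),
    ])
    def test_stoichiometry(self, n, ratio, expected):
        assert target_crosslink_count(n, ratio) == expected

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            target_crosslink_count(100, (0, 2))


class TestLocalRelax:
    def test_dimer_already_at_minimum_unchanged(self, lj_model):
        r0 = 2.0 ** (1 / 6) * 3.4
        m = Molecule(["X", "X"], [[0, 0, 0], [r0, 0, 0]])
        out = local_relax(m, lj_model, max_steps=50, step_size=0.01)
        assert np.linalg.norm(out.positions[1] - out.positions[0]) == \
            pytest.approx(r0, abs=1e-3)

    def test_compressed_dimer_reaches_analytic_minimum(self, lj_model):
        m = Molecule(["X", "X"], [[0, 0, 0], [0.9 * 3.4, 0, 0]])
        out = local_relax(m, lj_model, max_steps=500, step_size=0.05)
        assert np.linalg.norm(out.positions[1] - out.positions[0]) == \
            pytest.approx(2.0 ** (1 / 6) * 3.4, abs=1e-2 * 3.4)

    def test_zero_steps_returns_input(self, lj_model):
        m = Molecule(["X", "X"], [[0, 0, 0], [2.0, 0, 0]])
        out = local_relax(m, lj_model, max_steps=0)
        assert np.array_equal(out.positions, m.positions)

    def test_energy_non_increasing(self, lj_model, rng):
        coords = rng.uniform(0, 6, (6, 3))
        m = Molecule(["X"] * 6, coords)
        e0 = lj_model.total_energy([m])
        out = local_relax(m, lj_model, max_steps=100, step_size=0.02)
        assert lj_model.total_energy([out]) <= e0 + 1e-9


class TestBuildMatrix:
    def test_zero_target_leaves_chains_unchanged(self):
        cfg = BuilderConfig(**{**SMALL, "pva_sa_ratio": (10, 1),
                               "n_chains": 2, "chain_length": 2,
                               "box_lengths": (40.0, 40.0, 40.0)})
        # 4 monomers at 10:1 → round(0.4) = 0 crosslinks
        model = build_matrix(cfg)
        assert model.crosslinks == []
        assert model.composition()["sa_count"] == 0

    def test_two_parallel_chains_single_bridge(self):
        """Oracle: two 10-mer chains 5 Å apart have eligible pairs, so a
        target of one bridge must succeed with formation distance ≤ 10 Å."""
        from gelforge.network import _draw_eligible_pair, HydrogelModel
        from gelforge.structures import SimulationBox
        a = build_pva_chain(10, seed=0)
        b = build_pva_chain(10, seed=1)
        b.molecule.positions = b.molecule.positions + np.array([0, 5.0, 0])
        model = HydrogelModel(chains=[a, b],
                              box=SimulationBox([100, 100, 100]))
        # oracle: exhaustive eligible-pair enumeration
        eligible = []
        for sa_ in range(10):
            for sb in range(10):
                oa = a.molecule.positions[a.hydroxyl_sites[sa_]]
                ob = b.molecule.positions[b.hydroxyl_sites[sb]]
                if np.linalg.norm(oa - ob) <= 10.0:
                    eligible.append((sa_, sb))
        assert eligible, "construction guarantees eligible pairs"
        pair = _draw_eligible_pair(model, 10.0, np.random.default_rng(0))
        assert pair is not None
        (ca, sa_), (cb, sb), dist = pair
        assert ca != cb and dist <= 10.0
        assert (sa_, sb) in eligible or (sb, sa_) in eligible

    def test_shortfall_error_carries_partial_model(self):
        # two short chains far apart: no eligible pair for a nonzero target
        cfg = BuilderConfig(n_chains=2, chain_length=10,
                            box_lengths=(200.0, 200.0, 200.0),
                            min_separation=40.0, pva_sa_ratio=(10, 2),
                            relax_steps=0, n_guests=0)
        with pytest.raises(CrosslinkShortfallError) as err:
            build_matrix(cfg)
        assert err.value.achieved < 4
        assert err.value.model is not None
        assert len(err.value.model.chains) == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_contract_invariants_small_builds(self, seed):
        cfg = BuilderConfig(**SMALL, seed=seed)
        model = build_matrix(cfg)
        target = target_crosslink_count(
            cfg.n_chains * cfg.chain_length, cfg.pva_sa_ratio)
        assert len(model.crosslinks) == target
        used = []
        for x in model.crosslinks:
            assert x.chain_a != x.chain_b
            assert x.formation_distance <= cfg.crosslink_cutoff
            used += [(x.chain_a, x.site_a), (x.chain_b, x.site_b)]
        assert len(set(used)) == len(used)  # site uniqueness

    def test_deterministic_given_seed(self):
        cfg = BuilderConfig(**SMALL, seed=5)
        a = build_matrix(cfg)
        b = build_matrix(cfg)
        la = [(x.chain_a, x.site_a, x.chain_b, x.site_b) for x in a.crosslinks]
        lb = [(x.chain_a, x.site_a, x.chain_b, x.site_b) for x in b.crosslinks]
        assert la == lb

    def test_mass_bookkeeping(self):
        """Model mass = pristine chains + SA − one water per ester bond."""
        cfg = BuilderConfig(**SMALL, seed=2)
        model = build_matrix(cfg)
        comp = model.composition()
        rng = np.random.default_rng([cfg.seed, 101])
        seeds = rng.integers(0, 2 ** 31 - 1, size=cfg.n_chains)
        pristine = sum(
            molar_mass(build_pva_chain(cfg.chain_length, seed=int(s))
                       .molecule.formula()) for s in seeds)
        expected = pristine + comp["crosslink_count"] * SA - \
            comp["ester_bond_count"] * WATER
        assert comp["molar_mass_g_mol"] == pytest.approx(expected, abs=1e-6)


@pytest.fixture(scope="module")
def small_model():
    return build_matrix(BuilderConfig(**SMALL, seed=1))


@pytest.fixture(scope="module")
def guest_model():
    return build_matrix(BuilderConfig(**SMALL, seed=7))


class TestGrafting:

    def test_cd_composition_exact(self):
        cd, n_primary = make_gamma_cyclodextrin(0)
        assert cd.formula().composition == {"C": 48, "H": 80, "O": 40}
        assert n_primary == 8

    def test_zero_grafts_is_identity(self, small_model):
        before = small_model.composition()
        graft_cyclodextrins(small_model, 0, seed=1)
        assert small_model.composition() == before

    def test_graft_count_and_distinct_anchors(self, small_model):
        import copy
        model = copy.deepcopy(small_model)
        graft_cyclodextrins(model, 3, seed=2)
        comp = model.composition()
        assert comp["cd_count"] == 3
        anchors = {(g.chain, g.site) for g in model.grafted_cds}
        assert len(anchors) == 3
        # each graft costs one chain site and two ester bonds (SA + CD)
        assert comp["sa_count"] == comp["crosslink_count"] + 3
        assert comp["ester_bond_count"] == \
            2 * comp["crosslink_count"] + 2 * 3

    def test_graft_mass_bookkeeping(self, small_model):
        import copy
        model = copy.deepcopy(small_model)
        m0 = model.total_mass()
        graft_cyclodextrins(model, 2, seed=3)
        added = 2 * (SA + molar_mass("C48H80O40")) - 4 * WATER
        assert model.total_mass() == pytest.approx(m0 + added, abs=1e-6)

    def test_capacity_error_names_available(self, small_model):
        import copy
        model = copy.deepcopy(small_model)
        with pytest.raises(CapacityError) as err:
            graft_cyclodextrins(model, 10_000, seed=4)
        assert 0 <= err.value.available < 10_000


class TestPlaceGuests:
    def test_separation_contract(self, guest_model):
        import copy
        m = copy.deepcopy(guest_model)
        guest, _ = make_guest_stub(0)
        place_guests(m, guest, n_guests=5, min_distance=8.0, seed=1)
        assert len(m.guests) == 5
        gel = m.gel_coordinates()
        from scipy.spatial import cKDTree
        tree = cKDTree(gel)
        for i, g in enumerate(m.guests):
            assert tree.query(g.positions)[0].min() >= 8.0
            for j, h in enumerate(m.guests):
                if i < j:
                    d = np.min(np.linalg.norm(
                        g.positions[:, None] - h.positions[None], axis=-1))
                    assert d >= 8.0

    def test_zero_guests_unchanged(self, guest_model):
        import copy
        m = copy.deepcopy(guest_model)
        place_guests(m, make_guest_stub(0)[0], n_guests=0, seed=1)
        assert m.guests == []

    def test_impossible_distance_raises(self, guest_model):
        import copy
        m = copy.deepcopy(guest_model)
        with pytest.raises(PlacementError):
            place_guests(m, make_guest_stub(0)[0], n_guests=3,
                         min_distance=500.0, seed=1, box_margin=5.0,
                         attempt_budget=100)
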