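import numpy as np
import pytest

import ionsite as isite
from ionsite.fixtures import make_born_ion, make_dipole, make_random_cluster
from ionsite.grid import grid_to_world
from ionsite.ions import IonSpec
from ionsite.ranking import (SiteQueue, enumerate_candidates, passes_clash,
                             passes_proximity, predict, predict_full,
                             rank_sites, site_energy)
from ionsite.solver import SolverConfig
from ionsite.structure import Atom, Structure

from conftest import exhaustive_predict


class TestSiteEnergy:
    def test_zero_potential_in_bulk_is_zero(self, calcium):
        assert site_energy(0.0, 80.0, calcium, eps_w=80.0) == pytest.approx(0.0)

    def test_kT_to_kcal_conversion(self, calcium):
        # phi = -5 kT/e, z = +2, bulk eps: 2*(-5)*0.59249 kcal/mol
        val = site_energy(-5.0, 80.0, calcium, eps_w=80.0)
        assert val == pytest.approx(-5.925, abs=2e-3)

    def test_pure_desolvation_term(self, calcium):
        # phi = 0, eps 2: four times the z=1 Born value of ~40.47
        val = site_energy(0.0, 2.0, calcium, eps_w=80.0)
        assert val == pytest.approx(161.9, abs=0.1)

    def test_desolvation_can_be_excluded(self, calcium):
        val = site_energy(0.0, 2.0, calcium, eps_w=80.0,
                          include_desolvation=False)
        assert val == pytest.approx(0.0)


class TestEnumerateCandidates:
    def test_counts_match_brute_force_sphere_test(self):
        s = make_born_ion(1.0, 2.0)
        g = isite.GridSpec.centered((0, 0, 0), n=13, scale=2.0)
        mask = enumerate_candidates(g, s)
        expected = 0
        for i in range(1, 12):
            for j in range(1, 12):
                for k in range(1, 12):
                    p = grid_to_world(g, (i, j, k))
                    if np.linalg.norm(p) > 2.0:
                        expected += 1
        assert mask.sum() == expected
        # nodes inside the sphere excluded, e.g. the center
        assert not mask[6, 6, 6]

    def test_boundary_nodes_never_candidates(self):
        s = make_born_ion(1.0, 2.0)
        g = isite.GridSpec.centered((0, 0, 0), n=13, scale=2.0)
        mask = enumerate_candidates(g, s)
        assert not mask[0].any() and not mask[-1].any()
        assert not mask[:, 0].any() and not mask[:, :, -1].any()

    def test_nonempty_for_any_valid_grid(self):
        s = make_random_cluster(10, seed=4)
        g = isite.build_grid(s, scale=2.0, perfil=70.0)
        assert enumerate_candidates(g, s).any()


class TestPriorityQueue:
    def test_pop_order_and_negative_retention(self):
        q = rank_sites({(0, 0, 1): -3.0, (0, 1, 0): -1.0,
                        (1, 0, 0): -2.0, (1, 1, 1): 5.0})
        assert len(q) == 3
        order = [q.pop()[0] for _ in range(3)]
        assert order == [-3.0, -2.0, -1.0]

    def test_all_positive_gives_empty_queue(self):
        q = rank_sites({(0, 0, 0): 0.0, (1, 1, 1): 2.5})
        assert len(q) == 0

    def test_matches_full_sort_on_random_energies(self):
        rng = np.random.default_rng(11)
        energies = {}
        for flat in rng.choice(25**3, size=10**4, replace=False):
            node = tuple(int(v) for v in np.unravel_index(flat, (25, 25, 25)))
            energies[node] = float(rng.normal())
        q = rank_sites(energies)
        popped = [q.pop() for _ in range(len(q))]
        expected = sorted((e, n) for n, e in energies.items() if e < 0.0)
        assert popped == [(e, n) for e, n in expected]

    def test_ties_break_lexicographically(self):
        q = rank_sites({(2, 0, 0): -1.0, (0, 0, 2): -1.0, (0, 2, 0): -1.0})
        assert [q.pop()[1] for _ in range(3)] == [(0, 0, 2), (0, 2, 0), (2, 0, 0)]


class TestFilters:
    def _one_atom(self):
        return Structure([Atom(1, "C", "F", "A", 1, np.zeros(3), 0.0, 1.5)],
                         label="f")

    def test_clash_inside_threshold_fails(self):
        ion = IonSpec("X", 1, clash_radius=2.0)
        assert not passes_clash((3.0, 0, 0), self._one_atom(), ion)

    def test_clash_exact_boundary_passes(self):
        # discard only if strictly closer than R_ion + R_atom
        ion = IonSpec("X", 1, clash_radius=2.0)
        assert passes_clash((3.5, 0, 0), self._one_atom(), ion)

    def test_clash_far_site_passes(self):
        ion = IonSpec("X", 1, clash_radius=2.0)
        assert passes_clash((50, 0, 0), self._one_atom(), ion)

    def test_proximity_empty_accepted_passes(self):
        assert passes_proximity((0, 0, 0), [])

    def test_proximity_strict_greater_than(self):
        assert not passes_proximity((5.9, 0, 0), [np.zeros(3)])
        assert not passes_proximity((6.0, 0, 0), [np.zeros(3)])
        assert passes_proximity((6.01, 0, 0), [np.zeros(3)])


class TestPredict:
    def test_zero_charge_structure_gives_empty_list(self, chloride):
        s = make_born_ion(0.0, 2.0)
        sites = predict(s, chloride, n_max=5, perfil=40.0)
        assert sites == []

    def test_rank1_in_first_allowed_shell(self, born_run, born_plus3, chloride):
        run = born_run
        assert run.sites, "attractive solute must yield sites"
        r1 = run.sites[0]
        d = np.linalg.norm(r1.position)
        standoff = chloride.clash_radius + born_plus3.atoms[0].radius
        assert d >= standoff
        assert d <= standoff + run.grid.h + 1e-9

    def test_like_charge_ion_finds_nothing_nearby(self, born_plus3, calcium):
        sites = predict(born_plus3, calcium, n_max=10, perfil=30.0)
        assert all(np.linalg.norm(s.position) > 10.0 for s in sites)

    def test_energies_negative_and_sorted(self, born_run):
        e = [s.energy for s in born_run.sites]
        assert all(v < 0 for v in e)
        assert e == sorted(e)
        assert [s.rank for s in born_run.sites] == list(range(1, len(e) + 1))

    def test_sites_carry_reporting_fields(self, born_run):
        r1 = born_run.sites[0]
        assert r1.local_eps >= 2.0 and r1.local_eps <= 80.0
        assert r1.desolv >= 0.0
        assert r1.neighbors, "nearest atom should be reported"
        atom, dist = r1.neighbors[0]
        assert dist == pytest.approx(np.linalg.norm(r1.position - atom.position))

    def test_nmax_caps_output(self, born_plus3, chloride):
        sites = predict(born_plus3, chloride, n_max=2, perfil=30.0)
        assert len(sites) == 2

    def test_determinism(self, born_plus3, chloride):
        a = predict(born_plus3, chloride, n_max=5, perfil=30.0)
        b = predict(born_plus3, chloride, n_max=5, perfil=30.0)
        assert len(a) == len(b)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.position, s2.position)
            assert s1.energy == s2.energy


class TestOracleEquivalence:
    """predict() must reproduce an exhaustive sort-and-filter scan exactly."""

    @pytest.mark.parametrize("fixture, ion_name, perfil", [
        ("born", "CL1", 30.0),
        ("dipole", "CL1", 55.0),
        ("cluster", "CA2", 75.0),
    ])
    def test_positions_and_ranks_match(self, fixture, ion_name, perfil):
        s = {"born": lambda: make_born_ion(3.0, 2.0),
             "dipole": lambda: make_dipole(q=1.2),
             "cluster": lambda: make_random_cluster(8, seed=3, spread=1.5,
                                                    net_charge=-2.0),
             }[fixture]()
        ion = isite.get_ion(ion_name)
        run = predict_full(s, ion, n_max=10, perfil=perfil)
        assert run.grid.n <= 33
        oracle = exhaustive_predict(s, ion, run, n_max=10)
        assert len(run.sites) == len(oracle)
        for site, (g_o, p_o) in zip(run.sites, oracle):
            assert np.array_equal(site.position, p_o)
            assert site.energy == pytest.approx(g_o, rel=1e-12)


class TestInvariantsOnEveryRun:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_filter_invariants(self, seed, chloride):
        s = make_random_cluster(12, seed=seed, spread=2.0, net_charge=3.0)
        run = predict_full(s, chloride, n_max=10, perfil=60.0)
        pos = [st.position for st in run.sites]
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                assert np.linalg.norm(pos[i] - pos[j]) > 6.0
            d = np.linalg.norm(s.positions - pos[i], axis=1)
            assert np.all(d >= chloride.clash_radius + s.radii)

    def test_charge_conjugation_symmetry(self):
        s = make_random_cluster(10, seed=9, spread=2.0, net_charge=2.0)
        neg = Structure([Atom(a.serial, a.name, a.residue_name, a.chain_id,
                              a.residue_number, a.position, -a.charge, a.radius)
                         for a in s.atoms], label="neg")
        anion = IonSpec("AN1", -1)
        cation = IonSpec("CAT1", +1)
        a = predict(s, anion, n_max=10, perfil=60.0)
        b = predict(neg, cation, n_max=10, perfil=60.0)
        assert len(a) == len(b)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.position, s2.position)
            assert s1.energy == s2.energy
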