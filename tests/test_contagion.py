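"""Nonlinear SIS/SIR contagion: closed forms, oracles and localization."""

import math

import numpy as np
import pytest

import hypercores as hc
from _oracles import sis_pair_expected_tau


@pytest.fixture(scope="module")
def pair():
    return hc.Hypergraph([("a", "b")])


class TestInfectionProbability:
    def test_no_infected_neighbours(self, single_triangle):
        assert hc.infection_probability("a", set(), single_triangle,
                                        lam=0.5) == 0.0

    def test_one_term_product(self, pair):
        lam = 0.3
        p = hc.infection_probability("a", {"b"}, pair, lam=lam, nu=1.0)
        assert p == pytest.approx(1 - math.exp(-lam), abs=1e-15)

    def test_two_hyperedge_composition(self):
        # j in hyperedges with 2 and 3 infected members, nu=2, lam=0.01:
        # p = 1 - exp(-0.01*(4 + 9)) = 1 - e^{-0.13}
        H = hc.Hypergraph([("j", "u", "v"), ("j", "x", "y", "z")])
        p = hc.infection_probability("j", {"u", "v", "x", "y", "z"}, H,
                                     lam=0.01, nu=2.0)
        assert p == pytest.approx(1 - math.exp(-0.13), abs=1e-12)

    def test_product_composition_identity(self, small_random_graphs):
        rng = np.random.default_rng(0)
        for H in small_random_graphs[:8]:
            nodes = list(H.nodes)
            infected = {v for v in nodes if rng.random() < 0.4}
            sus = [v for v in nodes if v not in infected]
            if not sus:
                continue
            j = sus[0]
            lam, nu = 0.2, 1.5
            p = hc.infection_probability(j, infected, H, lam=lam, nu=nu)
            prod = 1.0
            for e in H.hyperedges:
                if j in e:
                    i_e = len(e & infected)
                    prod *= 1 - (1 - math.exp(-lam * i_e ** nu))
            assert p == pytest.approx(1 - prod, abs=1e-12)

    def test_pairwise_limit_matches_classical_sis(self):
        # nu=1 on an all-pairs hypergraph: p = 1 - exp(-lam * #infected nbrs)
        H = hc.Hypergraph([("j", "a"), ("j", "b"), ("j", "c"), ("a", "b")])
        p = hc.infection_probability("j", {"a", "b"}, H, lam=0.4, nu=1.0)
        assert p == pytest.approx(1 - math.exp(-0.4 * 2), abs=1e-12)

    def test_negative_lambda_rejected(self, pair):
        with pytest.raises(ValueError):
            hc.infection_probability("a", {"b"}, pair, lam=-0.1)


class TestSIS:
    def test_immediate_extinction(self, single_triangle):
        params = hc.ContagionParams(lam=0.0, mu=1.0, model="SIS", T=5,
                                    burn_in=0, n_runs=20, seed=1)
        res = hc.run_sis(single_triangle, params)
        assert res.n_extinct == 20 and res.n_valid == 0

    def test_absorbing_all_infected_limit(self, toy):
        # mu ~ 0 on the toy: within the seed's component tau/T -> 1
        params = hc.ContagionParams(lam=0.9, mu=1e-9, model="SIS", T=50,
                                    burn_in=200, n_runs=10, seed=3)
        res = hc.run_sis(toy, params)
        frac = res.tau_fraction()
        # the toy is hyperedge-connected, so every node saturates
        assert all(frac[v] == pytest.approx(1.0) for v in toy.nodes)

    def test_occupancy_bound(self, toy):
        params = hc.ContagionParams(lam=0.05, mu=0.3, model="SIS", T=40,
                                    burn_in=20, n_runs=30, seed=5)
        res = hc.run_sis(toy, params)
        assert (res.tau.sum(axis=1) <= toy.N * params.T).all()
        assert (res.tau >= 0).all() and (res.tau <= params.T).all()

    def test_two_node_markov_chain_oracle(self, pair):
        lam, mu, burn_in, T = 2.0, 0.1, 10, 40
        n_runs = 3000
        params = hc.ContagionParams(lam=lam, mu=mu, nu=1.0, model="SIS",
                                    T=T, burn_in=burn_in, n_runs=n_runs,
                                    seed=11)
        res = hc.run_sis(pair, params)
        ok = ~res.excluded
        # seeds are uniform over {a, b}; the chain is symmetric, so compare
        # the node-averaged occupancy
        sim = res.tau[ok].mean(axis=1) / T
        ea, eb, _ = sis_pair_expected_tau(lam, mu, burn_in, T, seed_first=0)
        expected = (ea + eb) / 2
        se = sim.std(ddof=1) / math.sqrt(ok.sum())
        assert abs(sim.mean() - expected) <= 3 * se

    def test_deterministic_under_seed(self, toy):
        params = hc.ContagionParams(lam=0.1, mu=0.2, model="SIS", T=20,
                                    burn_in=10, n_runs=10, seed=77)
        a = hc.run_sis(toy, params)
        b = hc.run_sis(toy, params)
        assert np.array_equal(a.tau, b.tau)
        assert np.array_equal(a.excluded, b.excluded)


class TestSIR:
    def test_lambda_zero_gives_size_one(self, toy):
        params = hc.ContagionParams(lam=0.0, mu=0.5, model="SIR",
                                    n_runs=50, seed=2)
        res = hc.run_sir_seed(toy, params, 1)
        assert (res.sizes == 1).all()

    def test_component_reachability_bound(self):
        H = hc.Hypergraph([("a", "b", "c"), ("d", "e")])
        params = hc.ContagionParams(lam=0.99, mu=0.5, model="SIR",
                                    n_runs=40, seed=4)
        res = hc.run_sir_seed(H, params, "a")
        assert (res.sizes <= 3).all()

    def test_two_node_closed_form(self, pair):
        # mean R_inf = 1 + q / (1 - (1-q)(1-mu)) with q = 1 - e^{-lam}
        lam, mu = 0.5, 0.4
        q = 1 - math.exp(-lam)
        expected = 1 + q / (1 - (1 - q) * (1 - mu))
        params = hc.ContagionParams(lam=lam, mu=mu, model="SIR",
                                    n_runs=10_000, seed=8)
        res = hc.run_sir_seed(pair, params, "a")
        assert abs(res.mean_final_size - expected) <= 3 * res.stderr

    def test_monotone_in_lambda(self, planted):
        H, _ = planted
        means = []
        for lam in (0.02, 0.1, 0.4):
            params = hc.ContagionParams(lam=lam, mu=0.3, model="SIR",
                                        n_runs=150, seed=6)
            means.append(hc.run_sir_seed(H, params, 0).mean_final_size)
        assert means[0] <= means[1] <= means[2]

    def test_deterministic_under_seed(self, toy):
        params = hc.ContagionParams(lam=0.2, mu=0.4, model="SIR",
                                    n_runs=30, seed=9)
        a = hc.run_sir_seed(toy, params, 5)
        b = hc.run_sir_seed(toy, params, 5)
        assert np.array_equal(a.sizes, b.sizes)


class TestAggregation:
    def test_constant_field(self, toy):
        prof = hc.decompose(toy)
        values = {v: 0.7 for v in toy.nodes}
        table = hc.aggregate_by_core(values, prof)
        assert np.allclose(table["mean"], 0.7)

    def test_full_core_equals_global_mean(self, single_triangle):
        prof = hc.decompose(single_triangle)
        values = {"a": 0.1, "b": 0.5, "c": 0.9}
        table = hc.aggregate_by_core(values, prof)
        cell = table[(table.m == 2) & (table.k == 1)]["mean"].iloc[0]
        assert cell == pytest.approx(0.5)

    def test_node_mismatch_raises(self, toy):
        prof = hc.decompose(toy)
        with pytest.raises(ValueError):
            hc.aggregate_by_core({1: 0.2}, prof)

    def test_sis_localizes_on_planted_core(self, planted):
        # directional check: the planted deep-core cell should outrun the
        # periphery average in most replicates (full version in acceptance)
        H, core = planted
        prof = hc.decompose(H)
        periphery = [v for v in H.nodes if v not in core]
        wins = 0
        reps = 10
        for r in range(reps):
            params = hc.ContagionParams(lam=0.05, nu=1.5, mu=0.1,
                                        model="SIS", T=150, burn_in=100,
                                        n_runs=10, seed=(100, r))
            frac = hc.run_sis(H, params).tau_fraction()
            core_avg = np.mean([frac[v] for v in core])
            peri_avg = np.mean([frac[v] for v in periphery])
            wins += core_avg > peri_avg
        assert wins >= 9
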