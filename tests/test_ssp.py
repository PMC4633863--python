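"""Structural-plasticity proposals, acceptance and the full loop."""

import numpy as np
import pytest
from scipy import stats

from evoneuro.dynamics import DynamicsParams, EnsembleState
from evoneuro.landscapes import DirectionalLandscape, StabilizingLandscape
from evoneuro.networks import Topology, make_complete, make_explicit
from evoneuro.ssp import (
    SSPParams,
    disbanding_probability,
    metropolis_accept,
    propose_disbanding,
    propose_random_rewire,
    propose_synaptogenesis,
    records_to_frame,
    run_ssp,
    save_topology_snapshots,
)


def _uniform_state(n, rho_value=0.5):
    topo = make_complete(n)
    rho = np.full(n, float(rho_value))
    return EnsembleState(topo, rho, np.zeros((n, n)))


class TestSynaptogenesis:
    def test_complete_graph_has_no_candidates(self, rng):
        st = _uniform_state(4)
        assert propose_synaptogenesis(st, st.topology, rng) is None

    def test_uniform_when_firing_probabilities_equal(self, rng):
        st = _uniform_state(4, 0.7)
        topo = Topology(4, ((0, 1),))  # five unconnected pairs
        counts = {}
        n_draws = 5000
        for _ in range(n_draws):
            e = propose_synaptogenesis(st, topo, rng)
            counts[e] = counts.get(e, 0) + 1
        obs = np.array(list(counts.values()))
        chi2, p = stats.chisquare(obs)
        assert len(counts) == 5
        assert p > 0.001

    def test_certain_pair_chosen_almost_surely(self, rng):
        topo = Topology(4, ())
        rho = np.array([1.0, 1.0, 0.0, 0.0])
        st = EnsembleState(topo, rho, np.zeros((4, 4)))
        for _ in range(50):
            assert propose_synaptogenesis(st, topo, rng) == (0, 1)

    def test_sampling_matches_cofireing_weights(self, rng):
        # empirical frequencies against the normalized rho_i*rho_j weights
        topo = Topology(5, ())
        rho = np.array([0.9, 0.7, 0.5, 0.3, 0.1])
        st = EnsembleState(topo, rho, np.zeros((5, 5)))
        pairs = topo.non_edges()
        w = np.array([rho[i] * rho[j] for (i, j) in pairs])
        w = w / w.sum()
        n_draws = 20000
        counts = dict.fromkeys(pairs, 0)
        for _ in range(n_draws):
            counts[propose_synaptogenesis(st, topo, rng)] += 1
        obs = np.array([counts[p] for p in pairs])
        chi2, p = stats.chisquare(obs, f_exp=w * n_draws)
        assert p > 0.001


class TestDisbanding:
    def test_maximal_removal_rate_at_zero_information(self):
        assert disbanding_probability(0.0, r_max=0.8, gamma=50.0) == 0.8

    def test_monotone_decreasing_in_information(self):
        grid = np.linspace(0.0, 0.5, 100)
        r = [disbanding_probability(h) for h in grid]
        assert all(a >= b for a, b in zip(r, r[1:]))

    def test_negative_information_rejected(self):
        with pytest.raises(ValueError):
            disbanding_probability(-0.1)

    def test_empty_graph_no_removals(self, rng):
        st = EnsembleState(Topology(3, ()), np.full(3, 0.5), np.zeros((3, 3)))
        assert propose_disbanding(st, st.topology, rng) == []

    def test_informative_edges_survive_longer(self, rng):
        # an edge with substantial weight (hence information) is flagged for
        # removal less often than a zero-weight edge
        from conftest import directional_equilibrium_state

        tri = directional_equilibrium_state(
            np.array([[0.0, 0.5, 0.4], [0.5, 0.0, 0.45], [0.4, 0.45, 0.0]]), S=2.0
        )
        topo = make_explicit(5, [(0, 1), (0, 2), (1, 2), (3, 4)])
        rho = np.concatenate([tri.rho, [0.8, 0.8]])
        phi = np.zeros((5, 5))
        phi[:3, :3] = tri.phi  # edge (3,4) keeps weight 0
        st = EnsembleState(topo, rho, phi)
        L = DirectionalLandscape(S=2.0)
        removed = dict.fromkeys(topo.edges, 0)
        n_sweeps = 1000
        for _ in range(n_sweeps):
            for e in propose_disbanding(st, topo, rng, landscape=L):
                removed[e] += 1
        assert removed[(0, 1)] < removed[(3, 4)]
        # zero-information edge removed at the maximal rate
        assert removed[(3, 4)] / n_sweeps == pytest.approx(1.0, abs=0.02)


class TestRandomRewire:
    def test_conserves_edge_count(self, rng):
        topo = make_explicit(5, [(0, 1), (1, 2), (3, 4)])
        move = propose_random_rewire(topo, u=1.0, rng=rng)
        drop, add = move
        new = topo.with_edges(remove=[drop], add=[add])
        assert new.d == topo.d

    def test_never_triggers_at_zero_probability(self, rng):
        topo = make_explicit(5, [(0, 1)])
        assert all(
            propose_random_rewire(topo, u=0.0, rng=rng) is None for _ in range(200)
        )

    def test_trigger_frequency_matches_u(self, rng):
        topo = make_explicit(5, [(0, 1), (1, 2)])
        u, n_calls = 0.2, 5000
        hits = sum(
            propose_random_rewire(topo, u=u, rng=rng) is not None
            for _ in range(n_calls)
        )
        se = np.sqrt(u * (1 - u) / n_calls)
        assert abs(hits / n_calls - u) < 4 * se

    def test_noop_on_empty_and_complete_graphs(self, rng):
        assert propose_random_rewire(Topology(4, ()), u=1.0, rng=rng) is None
        assert propose_random_rewire(make_complete(4), u=1.0, rng=rng) is None


class TestMetropolisAccept:
    def test_improvement_always_accepted(self, rng):
        assert all(metropolis_accept(1.0, 0.5, rng) for _ in range(100))

    def test_equal_fitness_accepted(self, rng):
        assert all(metropolis_accept(0.5, 0.5, rng) for _ in range(100))

    def test_acceptance_frequency_for_unit_deficit(self, rng):
        # Delta W = -1: empirical acceptance ~ e^{-1} within 3 binomial SE
        n_trials = 10_000
        acc = sum(metropolis_accept(-1.0, 0.0, rng) for _ in range(n_trials))
        p = np.exp(-1.0)
        se = np.sqrt(p * (1 - p) / n_trials)
        assert abs(acc / n_trials - p) < 3 * se


class TestRunSSP:
    def _params(self, **kw):
        base = dict(n_steps=60, seed=5, inner_t_max=300.0, u=0.05)
        base.update(kw)
        return SSPParams(**base)

    def test_chain_preserves_simple_graph_and_bookkeeping(self):
        L = StabilizingLandscape(beta=1.0, T=3)
        records = run_ssp(
            make_explicit(6, [(0, 1), (2, 3)]),
            L,
            DynamicsParams(lam=0.01),
            self._params(),
            keep_states=True,
        )
        assert len(records) == 60
        best = -np.inf
        for r in records:
            # Topology construction itself audits self/multi edges
            assert 0 <= r.d <= 15
            best = max(best, r.current_fitness)
            assert r.running_best == pytest.approx(best)
            a = r.topology.adjacency()
            assert not a.diagonal().any()

    def test_rejected_steps_keep_current_topology(self):
        L = StabilizingLandscape(beta=1.0, T=3)
        records = run_ssp(
            make_explicit(6, [(0, 1), (2, 3)]),
            L,
            DynamicsParams(lam=0.01),
            self._params(n_steps=40),
            keep_states=True,
        )
        prev = None
        for r in records:
            if prev is not None and not r.accepted:
                assert r.topology.edges == prev.topology.edges
            prev = r

    def test_weight_policies_and_frame_roundtrip(self, tmp_path):
        L = StabilizingLandscape(beta=1.0, T=3)
        for policy in ("reset-all", "keep-and-randomize-new"):
            records = run_ssp(
                make_explicit(5, [(0, 1)]),
                L,
                DynamicsParams(lam=0.01),
                self._params(n_steps=15, weight_policy=policy),
                keep_states=True,
            )
            df = records_to_frame(records)
            assert list(df.columns[:4]) == ["step", "moves", "d", "fitness"]
        save_topology_snapshots(records, tmp_path)
        assert any(tmp_path.iterdir())

    def test_costless_search_approaches_optimum_and_connects_active_loci(self):
        # without synapse costs the chain should find near-optimal circuits
        # whose active neurons form a single connected component
        import networkx as nx

        from evoneuro.networks import make_er

        L = StabilizingLandscape(beta=2.0, T=5)
        best_fit, connected = 0.0, False
        for seed in (1, 2):
            records = run_ssp(
                make_er(8, 0.45, seed=seed),
                L,
                DynamicsParams(lam=0.01),
                SSPParams(n_steps=150, k_cost=0.0, seed=seed, inner_t_max=1500.0),
                keep_states=True,
            )
            fits = [r.running_best for r in records]
            assert all(a <= b + 1e-12 for a, b in zip(fits, fits[1:]))
            final = records[-1]
            if final.current_fitness > best_fit:
                best_fit = final.current_fitness
                active = np.nonzero(final.state.rho > 0.5)[0]
                if len(active) == 5:
                    sub = final.topology.to_networkx().subgraph(active)
                    connected = nx.is_connected(sub)
        assert best_fit > 0.85
        assert connected
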