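"""Coupled selection-switching-learning dynamics."""

import numpy as np
import pytest

from evoneuro.dynamics import (
    DynamicsParams,
    EnsembleState,
    convergence_time,
    integrate,
    mean_activity,
    phi_rate,
    random_initial_state,
    rho_rate,
    switching_probability,
)
from evoneuro.fixtures import euler_oracle, exact_balance_root
from evoneuro.landscapes import DirectionalLandscape, StabilizingLandscape
from evoneuro.networks import make_complete, make_explicit


def _state(topo, rho, phi):
    return EnsembleState(topo, np.asarray(rho, float), np.asarray(phi, float))


class TestSwitchingRule:
    """Contracts of the activity rule (the transcription test)."""

    def test_naive_neuron_switches_at_one_half(self):
        assert switching_probability(0.0) == pytest.approx(0.5)

    def test_vanishes_for_strong_drive(self):
        assert switching_probability(6.0) < 1e-9
        assert switching_probability(-6.0) < 1e-9

    def test_monotone_non_increasing_in_activity(self):
        grid = np.linspace(0.0, 5.0, 200)
        m = switching_probability(grid)
        assert np.all(np.diff(m) <= 0)

    def test_bounded_in_half_open_interval(self):
        grid = np.linspace(-8, 8, 400)
        m = switching_probability(grid)
        assert np.all(m > 0) and np.all(m <= 0.5)


class TestMeanActivity:
    def test_zero_weights_give_zero_activity(self):
        topo = make_complete(4)
        st = _state(topo, [0.9, 0.1, 0.5, 0.7], np.zeros((4, 4)))
        assert np.all(mean_activity(st) == 0)

    def test_unbiased_inputs_give_zero_activity(self, rng):
        topo = make_complete(5)
        st = random_initial_state(topo, rng, 0.0, 0.5)
        st.rho[:] = 0.5
        np.testing.assert_allclose(mean_activity(st), 0.0, atol=1e-15)

    def test_hand_computed_three_neuron_case(self):
        topo = make_complete(3)
        phi = np.array([[0, 0.2, -0.1], [0.3, 0, 0.0], [0.1, 0.4, 0]])
        rho = np.array([1.0, 0.0, 0.75])
        st = _state(topo, rho, phi * topo.adjacency())
        # Xbar = (1, -1, 0.5)
        assert mean_activity(st, 0) == pytest.approx(0.2 * -1 + -0.1 * 0.5)
        assert mean_activity(st, 1) == pytest.approx(0.3 * 1)
        assert mean_activity(st, 2) == pytest.approx(0.1 * 1 + 0.4 * -1)


class TestRhoRate:
    def test_boundaries_absorbing_without_switching(self):
        # strong drive (M ~ 0) and rho in {0,1}: no motion
        topo = make_complete(2)
        st = _state(topo, [1.0, 0.0], [[0, 8.0], [8.0, 0]])
        rate = rho_rate(st, DirectionalLandscape(S=3.0))
        np.testing.assert_allclose(rate, 0.0, atol=1e-20)

    def test_flat_landscape_and_no_switching_is_stationary(self):
        topo = make_complete(2)
        st = _state(topo, [0.2, 0.8], [[0, 8.0], [8.0, 0]])
        rate = rho_rate(st, DirectionalLandscape(S=0.0))
        np.testing.assert_allclose(rate, 0.0, atol=1e-9)

    def test_rejects_probabilities_outside_unit_interval(self):
        topo = make_complete(2)
        st = _state(topo, [0.3, 0.8], np.zeros((2, 2)))
        st.rho[0] = 1.5  # corrupt after validation
        with pytest.raises(ValueError):
            rho_rate(st, DirectionalLandscape(S=1.0))

    def test_long_integration_hits_balance_root(self):
        # constant gradient, naive switching: the equilibrium must equal the
        # root of the rate function found independently by bisection
        S = 5.0
        root = exact_balance_root(S, 0.5)
        topo = make_complete(3)
        st = _state(topo, [0.6, 0.6, 0.6], np.zeros((3, 3)))
        traj = integrate(st, DynamicsParams(lam=0.0, t_max=3000.0), DirectionalLandscape(S=S))
        np.testing.assert_allclose(traj.rho[-1], root, atol=1e-5)


class TestPhiRate:
    def test_no_learning_no_weight_change(self, rng):
        topo = make_complete(4)
        st = random_initial_state(topo, rng, 0.0, 0.5)
        assert np.all(phi_rate(st, lam=0.0) == 0)

    def test_unbiased_ensemble_is_stationary_for_weights(self, rng):
        topo = make_complete(4)
        st = random_initial_state(topo, rng, 0.0, 0.5)
        st.rho[:] = 0.5
        np.testing.assert_allclose(phi_rate(st, lam=0.1), 0.0, atol=1e-15)

    def test_off_topology_entries_stay_zero(self, rng):
        star = make_explicit(5, [(0, i) for i in range(1, 5)])
        st = random_initial_state(star, rng, 0.0, 0.3)
        rate = phi_rate(st, lam=0.1)
        assert np.all(rate[~star.adjacency()] == 0)

    def test_oja_incoming_norm_converges_to_unity(self):
        # all-on three-neuron circuit: the incoming weight vector of each
        # neuron approaches the unit-norm Oja fixed point
        topo = make_complete(3)
        st = _state(topo, [1.0, 1.0, 1.0], np.full((3, 3), 0.05) * topo.adjacency())
        traj = integrate(
            st, DynamicsParams(lam=0.05, t_max=3000.0), DirectionalLandscape(S=5.0)
        )
        norms = np.linalg.norm(traj.phi[-1], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-4)


class TestIntegrate:
    def test_pure_switching_relaxes_to_one_half(self, rng):
        topo = make_complete(4)
        st = random_initial_state(topo, rng)
        traj = integrate(st, DynamicsParams(lam=0.0, t_max=200.0), DirectionalLandscape(S=0.0))
        np.testing.assert_allclose(traj.rho[-1], 0.5, atol=1e-7)

    def test_probabilities_stay_in_unit_interval(self, rng):
        topo = make_complete(6)
        st = random_initial_state(topo, rng)
        traj = integrate(
            st,
            DynamicsParams(lam=0.01, t_max=3000.0),
            StabilizingLandscape(beta=0.5, T=4),
        )
        assert traj.rho.min() >= 0.0 and traj.rho.max() <= 1.0

    def test_weight_sparsity_preserved_along_trajectory(self, rng):
        star = make_explicit(5, [(0, i) for i in range(1, 5)])
        st = random_initial_state(star, rng)
        traj = integrate(
            st, DynamicsParams(lam=0.01, t_max=1000.0), DirectionalLandscape(S=3.0)
        )
        off = ~star.adjacency()
        assert np.all(traj.phi[:, off] == 0)

    def test_permutation_symmetry_of_identical_loci(self):
        # symmetric landscape + symmetric initial conditions: all loci follow
        # the same trajectory
        topo = make_complete(4)
        st = _state(topo, np.full(4, 0.42), np.full((4, 4), 0.005) * topo.adjacency())
        traj = integrate(
            st, DynamicsParams(lam=0.01, t_max=500.0), DirectionalLandscape(S=2.0)
        )
        assert np.max(np.ptp(traj.rho, axis=1)) < 1e-8

    def test_euler_oracle_agreement(self):
        # independent fixed-step re-integration of the same equations
        topo = make_complete(3)
        rng = np.random.default_rng(0)
        st = random_initial_state(topo, rng)
        L = DirectionalLandscape(S=2.0)
        t_end = 50.0
        traj = integrate(st.copy(), DynamicsParams(lam=0.05, t_max=t_end), L)
        rho_e, phi_e = euler_oracle(
            st.rho, st.phi, topo.adjacency(), L, lam=0.05, t_max=t_end, dt=2e-3
        )
        assert np.max(np.abs(traj.rho[-1] - rho_e)) < 1e-4

    def test_exact_backend_matches_approx_for_weak_selection(self, rng):
        topo = make_complete(4)
        st = random_initial_state(topo, rng)
        L = StabilizingLandscape(beta=0.02, T=3)
        t1 = integrate(st.copy(), DynamicsParams(lam=0.0, t_max=500.0), L)
        t2 = integrate(
            st.copy(), DynamicsParams(lam=0.0, t_max=500.0, backend="exact"), L
        )
        np.testing.assert_allclose(t1.rho[-1], t2.rho[-1], atol=5e-3)

    def test_learning_rate_regime_warning(self, rng):
        topo = make_complete(3)
        st = random_initial_state(topo, rng)
        with pytest.warns(UserWarning, match="not slower than selection"):
            integrate(st, DynamicsParams(lam=2.0, t_max=1.0), DirectionalLandscape(S=1.0))

    def test_equilibrium_independent_of_learning_rate(self):
        # the learnt equilibrium does not depend on lambda
        topo = make_complete(6)
        L = DirectionalLandscape(S=5.0)
        finals = []
        for lam in (1e-3, 1e-2):
            rng = np.random.default_rng(21)
            st = random_initial_state(topo, rng)
            traj = integrate(st, DynamicsParams(lam=lam, t_max=10_000.0), L)
            finals.append(traj.rho[-1])
        np.testing.assert_allclose(finals[0], finals[1], atol=1e-3)


class TestTrajectoryOutputs:
    def test_convergence_time_of_converged_trace_is_first_sample(self, rng):
        topo = make_complete(3)
        st = _state(topo, [0.99, 0.99, 0.99], np.zeros((3, 3)))
        traj = integrate(st, DynamicsParams(lam=0.0, t_max=100.0), DirectionalLandscape(S=5.0))
        assert convergence_time(traj, 0.5) == traj.t[0]

    def test_unattained_fraction_returns_sentinel(self, rng):
        topo = make_complete(3)
        st = random_initial_state(topo, rng)
        traj = integrate(st, DynamicsParams(lam=0.0, t_max=10.0), DirectionalLandscape(S=1.0))
        assert convergence_time(traj, 1.5) == -1.0

    def test_writer_emits_csv_and_summary(self, tmp_path, rng):
        topo = make_complete(3)
        st = random_initial_state(topo, rng)
        traj = integrate(st, DynamicsParams(lam=0.01, t_max=50.0), DirectionalLandscape(S=2.0))
        traj.write(tmp_path)
        assert (tmp_path / "trajectory.csv").exists()
        assert (tmp_path / "weights_final.csv").exists()
        assert (tmp_path / "summary.json").exists()

    def test_state_topology_consistency_enforced(self, rng):
        topo = make_complete(3)
        other = make_complete(4)
        st = random_initial_state(topo, rng)
        with pytest.raises(ValueError):
            integrate(st, DynamicsParams(), DirectionalLandscape(S=1.0), topology=other)
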