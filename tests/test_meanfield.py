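"""Mean-field dynamics: right-hand sides, integrators and closed forms."""

import math

import numpy as np
import pytest

from affective_dis import meanfield as mf
from affective_dis import network as nw


def _random_state(n, rng, scale=0.5):
    return (rng.normal(scale=scale, size=n) + 1j * rng.normal(scale=scale, size=n),
            rng.uniform(-1, 1, size=n))


class TestFullSystem:
    def test_decoupled_field_decays_as_linear_mode(self):
        """g = J = 0: E(t) = E(0) e^{(-i Delta - kappa) t}."""
        pars = mf.AgentParams(n=1, Delta=0.7, Gamma=0.0, gamma_plus=0.0,
                              sigma_z0=0.0, g=0.0)
        init = mf.MeanFieldState(sigma_x=np.zeros(1), sigma_y=np.zeros(1),
                                 sigma_z=np.zeros(1), E=np.array([1.0 + 0j]))
        traj = mf.integrate("full", None, pars, mf.NO_COUPLING, init,
                            t_end=5.0, dt_out=0.05)
        expected = np.exp((-1j * 0.7 - 1.0) * traj.t)
        assert np.max(np.abs(traj.E[:, 0] - expected)) < 1e-7

    def test_neutral_fixed_point_has_zero_derivative(self):
        pars = mf.AgentParams(n=3, Delta=0.2, Gamma=0.1, gamma_plus=0.4,
                              sigma_z0=0.6, g=0.5)
        de, dp, dsz = mf.rhs_full(np.zeros(3, complex), np.zeros(3, complex),
                                  np.full(3, 0.6), pars)
        assert np.all(de == 0) and np.all(dp == 0) and np.all(dsz == 0)

    def test_field_settles_onto_adiabatic_manifold(self):
        """After transients E_i tracks -g p_i (Delta + i kappa)/(Delta^2+kappa^2)."""
        pars = mf.AgentParams(n=1, Delta=0.0, Gamma=0.01, gamma_plus=0.0,
                              sigma_z0=0.0, g=0.5, kappa=5.0)
        init = mf.initial_state(1, epsilon=0.3, seed=1)
        traj = mf.integrate("full", None, pars, mf.NO_COUPLING, init,
                            t_end=150.0, dt_out=0.5)
        late = traj.t > 50.0
        p_late = traj.p[late, 0]
        e_pred = mf.adiabatic_field(p_late, pars)
        # first-order tracking error scales like (atomic rate)/kappa
        assert np.max(np.abs(traj.E[late, 0] - e_pred)) < 5e-3

    def test_shape_mismatch_rejected(self):
        pars = mf.AgentParams(n=2, Delta=0.0, Gamma=0.0, gamma_plus=0.0,
                              sigma_z0=0.0, g=0.5)
        with pytest.raises(ValueError):
            mf.rhs_full(np.zeros(3, complex), np.zeros(2, complex), np.zeros(2), pars)


class TestAdiabaticField:
    def test_zero_amplitudes_give_zero_field(self):
        pars = mf.AgentParams(n=4, Delta=0.3, Gamma=0.1, gamma_plus=0.1,
                              sigma_z0=0.5, g=0.5)
        assert np.all(mf.adiabatic_field(np.zeros(4, complex), pars) == 0)

    def test_uncoupled_reduces_to_zeroth_order(self, rng):
        pars = mf.AgentParams(n=3, Delta=np.array([0.0, 0.4, -0.2]), Gamma=0.1,
                              gamma_plus=0.1, sigma_z0=0.5, g=0.5)
        p, _ = _random_state(3, rng)
        e = mf.adiabatic_field(p, pars, mf.NO_COUPLING)
        lam = (pars.Delta + 1j) / (pars.Delta**2 + 1.0)
        assert np.allclose(e, -0.5 * p * lam)

    def test_two_node_correction_matches_hand_expansion(self):
        """N=2 path, Delta=0: E_0 = -g p_0 (i/kappa) - i J g p_1 (i/kappa)."""
        pars = mf.AgentParams(n=2, Delta=0.0, Gamma=0.1, gamma_plus=0.1,
                              sigma_z0=0.5, g=0.5)
        cp = mf.CouplingSpec(J_R=0.02)
        import networkx as nx

        net = nw.NetworkModel(graph=nx.path_graph(2))
        p = np.array([0.3 + 0.1j, -0.2 + 0.4j])
        e = mf.adiabatic_field(p, pars, cp, net)
        hand = -0.5j * p - 1j * 0.02 * 0.5 * (1j * p[::-1])
        assert np.allclose(e, hand, atol=1e-15)


class TestReducedComplex:
    def test_relaxation_to_pump_balance_without_field(self):
        pars = mf.AgentParams(n=1, Delta=0.0, Gamma=0.1, gamma_plus=0.4,
                              sigma_z0=0.7, g=0.5)
        dp, dsz = mf.rhs_reduced_complex(np.zeros(1, complex), np.array([0.2]), pars)
        assert dp[0] == 0
        assert dsz[0] == pytest.approx(0.4 * (0.7 - 0.2))

    def test_linear_growth_rate_above_threshold(self):
        """Frozen sz > sz_cr: |p| grows at C sz - Gamma (linearized eigenvalue)."""
        pars = mf.AgentParams(n=1, Delta=0.0, Gamma=0.05, gamma_plus=0.0,
                              sigma_z0=0.9, g=0.5)
        rate_pred = float(pars.C[0]) * 0.9 - 0.05
        p0 = 1e-8
        dp, _ = mf.rhs_reduced_complex(np.array([p0 + 0j]), np.array([0.9]), pars)
        assert (dp[0] / p0).real == pytest.approx(rate_pred, rel=1e-12)

    def test_network_term_vanishes_at_theta_half_pi(self, scale_free_60, rng):
        pars = mf.AgentParams(n=60, Delta=0.0, Gamma=0.1, gamma_plus=0.1,
                              sigma_z0=0.9, g=0.5)
        p, sz = _random_state(60, rng)
        cp_off = mf.CouplingSpec(J_R=0.0, J_I=0.05, Theta=math.pi / 2)
        dp_off, _ = mf.rhs_reduced_complex(p, sz, pars, cp_off, scale_free_60)
        dp_free, _ = mf.rhs_reduced_complex(p, sz, pars, mf.NO_COUPLING)
        assert np.allclose(dp_off, dp_free, atol=1e-15)

    def test_zero_g_with_coupling_rejected(self, scale_free_60):
        pars = mf.AgentParams(n=60, Delta=0.0, Gamma=0.1, gamma_plus=0.1,
                              sigma_z0=0.9, g=0.0)
        with pytest.raises(ValueError):
            mf.rhs_reduced_complex(np.ones(60, complex), np.zeros(60), pars,
                                   mf.CouplingSpec(J_R=0.01), scale_free_60)


class TestRealSystem:
    def test_matches_reduced_complex_at_random_states(self, scale_free_60, rng):
        """Exact equivalence under p = (sigma_x - i sigma_y)/2, with network."""
        n = 60
        pars = mf.AgentParams(n=n, Delta=0.3, Gamma=0.1, gamma_plus=0.5,
                              sigma_z0=0.99, g=0.5)
        cp = mf.CouplingSpec(J_R=0.01, J_I=0.02, Theta=2.0)
        for _ in range(100):
            sx, sy, sz = rng.normal(size=(3, n))
            dsx, dsy, dsz = mf.rhs_real(sx, sy, sz, pars, cp, scale_free_60)
            dp, dsz2 = mf.rhs_reduced_complex(
                0.5 * (sx - 1j * sy), sz, pars, cp, scale_free_60
            )
            assert np.max(np.abs(dp - 0.5 * (dsx - 1j * dsy))) < 1e-10
            assert np.max(np.abs(dsz - dsz2)) < 1e-10

    def test_radius_rate_identity_without_network(self, rng):
        """d(R^2)/dt from the component equations equals the closed identity."""
        n = 5
        pars = mf.AgentParams(n=n, Delta=0.2, Gamma=0.15, gamma_plus=0.3,
                              sigma_z0=0.8, g=0.5)
        for _ in range(20):
            sx, sy, sz = rng.normal(size=(3, n))
            dsx, dsy, dsz = mf.rhs_real(sx, sy, sz, pars)
            lhs = sx * dsx + sy * dsy + sz * dsz  # = R dR/dt
            state = mf.MeanFieldState(sigma_x=sx, sigma_y=sy, sigma_z=sz)
            rhs = mf.radius_rate_diagnostic(state, pars)
            assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_heterogeneous_detuning_with_coupling_rejected(self, scale_free_60):
        pars = mf.AgentParams(n=60, Delta=np.linspace(0, 0.5, 60), Gamma=0.1,
                              gamma_plus=0.1, sigma_z0=0.9, g=0.5)
        with pytest.raises(ValueError, match="common Delta"):
            mf.rhs_real(np.ones(60), np.ones(60), np.ones(60), pars,
                        mf.CouplingSpec(J_R=0.01), scale_free_60)


class TestClosedForms:
    def test_free_relaxation_reference_values(self):
        perp, sz, r = mf.closed_form_free(np.array([0.0]), C=0.25)
        assert (perp[0], sz[0], r[0]) == (1.0, -0.0, 1.0)
        perp, sz, r = mf.closed_form_free(np.array([1e3]), C=0.25)
        assert sz[0] == pytest.approx(-1.0, abs=1e-12)
        assert perp[0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_satisfies_equations_of_motion(self):
        """sech/tanh substituted into the undamped RHS leaves tiny residual."""
        c = 0.25
        pars = mf.AgentParams(n=1, Delta=0.0, Gamma=0.0, gamma_plus=0.0,
                              sigma_z0=0.0, g=0.5)
        t = np.linspace(-5, 5, 101)
        perp, sz, _ = mf.closed_form_free(t, C=c)
        # place the transverse component on the x axis (phase is free)
        for ti, pe, szi in zip(t, perp, sz):
            dsx, _, dsz = mf.rhs_real(np.array([pe]), np.zeros(1),
                                      np.array([szi]), pars)
            # analytic derivatives
            d_perp = -c * math.tanh(c * ti) / math.cosh(c * ti)
            d_sz = -c / math.cosh(c * ti) ** 2
            assert dsx[0] == pytest.approx(d_perp, abs=1e-10)
            assert dsz[0] == pytest.approx(d_sz, abs=1e-10)

    def test_integrated_trajectory_matches_closed_form(self, single_agent_free):
        init = mf.MeanFieldState(sigma_x=np.array([1.0]), sigma_y=np.zeros(1),
                                 sigma_z=np.zeros(1))
        traj = mf.integrate("real", None, single_agent_free, mf.NO_COUPLING,
                            init, t_end=50.0, dt_out=0.1)
        perp, sz, _ = mf.closed_form_free(traj.t, C=float(single_agent_free.C[0]))
        assert np.max(np.abs(traj.sigma_perp[:, 0] - perp)) < 1e-6
        assert np.max(np.abs(traj.sigma_z[:, 0] - sz)) < 1e-6

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            mf.closed_form_free(np.array([0.0]), C=0.0)


class TestIntegrate:
    def test_free_agents_reach_the_calm_pole(self, single_agent_free):
        """Undamped, unpumped agents relax to sigma_z = -1 by tau = 100."""
        init = mf.initial_state(1, epsilon=1e-2, seed=0)
        traj = mf.integrate("real", None, single_agent_free, mf.NO_COUPLING,
                            init, t_end=100.0, dt_out=0.5)
        assert traj.sigma_z[-1, 0] == pytest.approx(-1.0, abs=1e-3)

    def test_limit_cycle_frequency_matches_prediction(self, pumped_agent):
        init = mf.initial_state(1, seed=2)
        traj = mf.integrate("real", None, pumped_agent, mf.NO_COUPLING, init,
                            t_end=2000.0, dt_out=0.5)
        omega_pred = 0.1 * 0.5 / 1.0  # Gamma * Delta / kappa
        assert mf.measure_frequency(traj) == pytest.approx(omega_pred, rel=0.01)

    def test_polar_manifold_is_invariant(self, single_agent_free):
        init = mf.MeanFieldState(sigma_x=np.zeros(1), sigma_y=np.zeros(1),
                                 sigma_z=np.array([0.9]))
        traj = mf.integrate("real", None, single_agent_free, mf.NO_COUPLING,
                            init, t_end=50.0, dt_out=0.5)
        assert np.max(traj.sigma_perp) == 0.0

    def test_radius_conserved_without_damping(self, single_agent_free):
        init = mf.MeanFieldState(sigma_x=np.array([0.8]), sigma_y=np.zeros(1),
                                 sigma_z=np.array([0.6]))
        traj = mf.integrate("real", None, single_agent_free, mf.NO_COUPLING,
                            init, t_end=50.0, dt_out=0.1)
        assert np.max(np.abs(traj.R - 1.0)) < 1e-6

    def test_invalid_horizon_rejected(self, single_agent_free):
        with pytest.raises(ValueError):
            mf.integrate("real", None, single_agent_free, mf.NO_COUPLING,
                         mf.initial_state(1, seed=0), t_end=-1.0)


class TestFullVsReduced:
    def test_adiabatic_agreement_improves_with_scale_separation(self):
        """Terminal arousal agrees within 0.05; the trajectory-level
        discrepancy shrinks monotonically as kappa/Gamma grows."""
        diffs = []
        for kappa, t_end in ((1.0, 300.0), (3.0, 600.0), (10.0, 2000.0)):
            pars = mf.AgentParams(n=1, Delta=0.0, Gamma=0.1, gamma_plus=0.5,
                                  sigma_z0=0.99, g=0.5, kappa=kappa)
            init = mf.initial_state(1, seed=4)
            tr_full = mf.integrate("full", None, pars, mf.NO_COUPLING, init,
                                   t_end=t_end, dt_out=t_end / 500)
            tr_red = mf.integrate("reduced", None, pars, mf.NO_COUPLING, init,
                                  t_end=t_end, dt_out=t_end / 500)
            assert abs(tr_full.sigma_z[-1, 0] - tr_red.sigma_z[-1, 0]) < 0.05
            # transient window where the adiabatic error is visible
            c = float(pars.C[0])
            window = tr_full.t <= 8.0 / c
            diffs.append(np.max(np.abs(
                tr_full.sigma_z[window] - tr_red.sigma_z[window]
            )))
        assert diffs[0] > diffs[1] > diffs[2]


class TestLimitCycle:
    def test_reference_frequency(self, pumped_agent):
        amp, omega, locked = mf.limit_cycle(pumped_agent)
        assert omega == pytest.approx(0.05)
        assert locked == pytest.approx(0.1 / float(pumped_agent.C[0]))

    def test_zero_detuning_freezes_the_precession(self):
        pars = mf.AgentParams(n=1, Delta=0.0, Gamma=0.1, gamma_plus=0.5,
                              sigma_z0=0.99, g=0.5)
        _, omega, _ = mf.limit_cycle(pars)
        assert omega == 0.0

    def test_orbit_amplitude_and_lock_match_integration(self, pumped_agent):
        amp, _, locked = mf.limit_cycle(pumped_agent)
        traj = mf.integrate("real", None, pumped_agent, mf.NO_COUPLING,
                            mf.initial_state(1, seed=5), t_end=2000.0, dt_out=0.5)
        assert traj.sigma_z[-1, 0] == pytest.approx(locked, rel=0.01)
        assert traj.sigma_perp[-1, 0] == pytest.approx(amp, rel=0.01)

    def test_below_threshold_has_no_cycle(self):
        pars = mf.AgentParams(n=1, Delta=0.0, Gamma=0.3, gamma_plus=0.5,
                              sigma_z0=0.99, g=0.5)
        with pytest.raises(ValueError, match="no limit cycle"):
            mf.limit_cycle(pars)


class TestMeasureFrequency:
    def test_known_sinusoid(self):
        t = np.arange(0.0, 800.0, 0.5)
        traj = mf.Trajectory(t=t, sigma_x=np.cos(0.05 * t)[:, None],
                             sigma_y=np.zeros((len(t), 1)),
                             sigma_z=np.zeros((len(t), 1)))
        assert mf.measure_frequency(traj) == pytest.approx(0.05, abs=1e-4)

    def test_constant_signal_rejected(self):
        t = np.arange(0.0, 100.0, 0.5)
        traj = mf.Trajectory(t=t, sigma_x=np.ones((len(t), 1)),
                             sigma_y=np.zeros((len(t), 1)),
                             sigma_z=np.zeros((len(t), 1)))
        with pytest.raises(ValueError):
            mf.measure_frequency(traj)


class TestAgentParams:
    def test_pump_balance_from_rates(self):
        pars = mf.AgentParams.from_rates(n=1, Delta=0.0, Gamma=0.0,
                                         gamma_p=0.3, gamma_e=0.1, g=0.5)
        assert pars.sigma_z0[0] == pytest.approx(0.5)
        assert pars.gamma_plus[0] == pytest.approx(0.4)

    def test_balanced_pumping_is_neutral(self):
        pars = mf.AgentParams.from_rates(n=1, Delta=0.0, Gamma=0.0,
                                         gamma_p=0.3, gamma_e=0.3, g=0.5)
        assert pars.sigma_z0[0] == 0.0

    def test_rate_definitions(self):
        pars = mf.AgentParams(n=1, Delta=1.0, Gamma=0.1, gamma_plus=0.1,
                              sigma_z0=0.5, g=0.5)
        assert pars.C[0] == pytest.approx(0.125)    # kappa g^2/(Delta^2+kappa^2)
        assert pars.D[0] == pytest.approx(0.125)    # = Delta_tilde * C
        assert pars.D[0] == pytest.approx(pars.Delta_tilde[0] * pars.C[0])

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            mf.AgentParams(n=1, Delta=0.0, Gamma=-0.1, gamma_plus=0.0,
                           sigma_z0=0.0, g=0.5)

    def test_adiabatic_flag(self):
        pars = mf.AgentParams(n=1, Delta=0.0, Gamma=0.01, gamma_plus=0.02,
                              sigma_z0=0.0, g=0.5)
        assert pars.adiabatic_flag(mf.CouplingSpec(J_R=0.01))
        assert not pars.adiabatic_flag(mf.CouplingSpec(J_R=0.8))


def test_coupling_spec_complex_form():
    cp = mf.CouplingSpec(J_R=0.01, J_I=0.02, Theta=math.pi)
    assert cp.J_I_eff == pytest.approx(-0.02)
    assert cp.J == pytest.approx(0.01 - 0.02j)
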