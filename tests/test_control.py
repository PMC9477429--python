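"""Optimal-control machinery: objective, adjoints, sweep convergence."""

import math

import numpy as np
import pytest

from adcascade import (BiomarkerTrajectory, OCConfig, adjoint_rhs,
                       control_gradient, control_update,
                       forward_backward_sweep, get_drug, objective,
                       side_effect_weight, simulate)
from adcascade.control import solve_adjoint
from adcascade.model import integrate_grid


@pytest.fixture(scope="module")
def donanemab_cfg():
    return OCConfig(u_max=get_drug("donanemab").u_max_per_year,
                    T1=60.0, T2=61.5)


class TestSideEffect:
    def test_no_decay_at_treatment_start(self):
        assert side_effect_weight(100.0, 0.0, eps0=5, gamma=2) == 500.0

    def test_zero_amyloid_gives_zero_weight(self):
        assert side_effect_weight(0.0, 3.0) == 0.0

    def test_exponential_decay_value(self):
        assert side_effect_weight(100.0, 1.0, eps0=5, gamma=2) == \
            pytest.approx(500.0 * math.exp(-2.0))


class TestObjective:
    def test_constant_states_closed_form(self):
        t = np.linspace(60, 62, 41)
        a, c = 100.0, 20.0
        states = BiomarkerTrajectory(t, np.tile([a, 0, 0, 0, c], (41, 1)))
        cfg = OCConfig(u_max=1.0, T1=60, T2=62, alpha1=2.0, alpha2=3.0)
        J = objective(states, np.zeros(41), cfg)
        assert J == pytest.approx(2 * a + 3 * c + c * 2.0, rel=1e-12)

    def test_untreated_objective_ignores_side_effect_parameters(self,
                                                                ad_params):
        traj = simulate(ad_params, 60, 61.5, step=0.05)
        u = np.zeros(len(traj))
        j1 = objective(traj, u, OCConfig(u_max=1, T1=60, T2=61.5))
        j2 = objective(traj, u, OCConfig(u_max=1, T1=60, T2=61.5,
                                         eps0=99, gamma=0.1))
        assert j1 == j2

    def test_trapezoid_exact_on_linear_cognition(self):
        t = np.linspace(0.0, 1.0, 9)
        states = np.zeros((9, 5))
        states[:, 4] = t
        traj = BiomarkerTrajectory(t, states)
        cfg = OCConfig(u_max=1, T1=0.0, T2=1.0, alpha1=0.0, alpha2=0.0)
        assert objective(traj, np.zeros(9), cfg) == pytest.approx(0.5,
                                                                  abs=1e-10)

    def test_grid_mismatch_rejected(self, ad_params):
        traj = simulate(ad_params, 60, 61, step=0.5)
        with pytest.raises(ValueError):
            objective(traj, np.zeros(5), OCConfig(u_max=1, T1=60, T2=61))


class TestAdjointRhs:
    def test_only_running_cost_survives_at_zero(self, ad_params):
        cfg = OCConfig(u_max=1, T1=60, T2=62)
        d = adjoint_rhs([100, 10, 20, 0.5, 5], np.zeros(5), 0.0, 0.0,
                        ad_params, cfg)
        np.testing.assert_allclose(d, [0, 0, 0, 0, -1.0])

    def test_printed_form_matches_derived_when_no_tau_coupling(self,
                                                               ad_params):
        p = ad_params.with_(lambda_Ctau=0.0)
        state = [100, 10, 20, 0.5, 5]
        adj = [0.5, -0.2, 0.1, 0.3, 1.2]
        d1 = adjoint_rhs(state, adj, 0.1, 0.5, p,
                         OCConfig(u_max=1, T1=60, T2=62,
                                  adjoint_form="derived"))
        d2 = adjoint_rhs(state, adj, 0.1, 0.5, p,
                         OCConfig(u_max=1, T1=60, T2=62,
                                  adjoint_form="printed"))
        np.testing.assert_allclose(d1, d2)

    def test_adjoint_forms_differ_by_tau_coupling_term(self, ad_params):
        state = np.array([100, 10, 20, 0.5, 5.0])
        adj = np.array([0.0, 0, 0, 0, 2.0])
        der = adjoint_rhs(state, adj, 0.0, 0.0, ad_params,
                          OCConfig(u_max=1, T1=60, T2=62))
        pr = adjoint_rhs(state, adj, 0.0, 0.0, ad_params,
                         OCConfig(u_max=1, T1=60, T2=62,
                                  adjoint_form="printed"))
        gap = ad_params.lambda_Ctau * 10 / ad_params.K_C * 2.0
        assert der[4] - pr[4] == pytest.approx(gap)


class TestControlUpdate:
    def test_nonpositive_drive_clamps_to_zero(self):
        assert control_update(100.0, -0.5, 5.0, 1.0) == 0.0

    def test_large_drive_clamps_to_umax(self):
        assert control_update(100.0, 10.0, 5.0, 1.0) == 1.0

    def test_interior_arithmetic(self):
        assert control_update(100.0, 0.01, 5.0, 1.0) == pytest.approx(0.1)

    def test_vanishing_penalty_degenerates_to_bang_bang(self):
        assert control_update(100.0, 0.5, 0.0, 0.7) == 0.7
        assert control_update(100.0, -0.5, 0.0, 0.7) == 0.0


class TestSweep:
    def test_zero_umax_returns_untreated_solution(self, slow_params):
        cfg = OCConfig(u_max=0.0, T1=60, T2=61.5)
        sol = forward_backward_sweep(slow_params, cfg)
        assert np.all(sol.u == 0)
        assert sol.converged
        untreated = simulate(slow_params, 50, 61.5, step=cfg.step)
        assert sol.states.C[-1] == pytest.approx(untreated.C[-1], rel=1e-9)

    def test_transversality_conditions_exact(self, slow_params,
                                             donanemab_cfg):
        sol = forward_backward_sweep(slow_params, donanemab_cfg)
        assert sol.adjoints[-1, 0] == donanemab_cfg.alpha1
        assert sol.adjoints[-1, 4] == donanemab_cfg.alpha2
        assert np.all(sol.adjoints[-1, 1:4] == 0.0)

    def test_control_stays_in_box(self, slow_params, donanemab_cfg):
        sol = forward_backward_sweep(slow_params, donanemab_cfg)
        assert np.all(sol.u >= 0.0)
        assert np.all(sol.u <= donanemab_cfg.u_max)

    def test_interior_first_order_condition(self, slow_params,
                                            donanemab_cfg):
        sol = forward_backward_sweep(slow_params, donanemab_cfg)
        g = control_gradient(sol.states, sol.adjoints, sol.u, donanemab_cfg)
        # points still relaxing onto the bound sit within ~tol*u_max of
        # it; treat only comfortably interior nodes as unconstrained
        margin = 10 * donanemab_cfg.tol * donanemab_cfg.u_max
        interior = (sol.u > margin) & (sol.u < donanemab_cfg.u_max - margin)
        assert interior.any()
        scale = np.max(np.abs(sol.states.Abeta * sol.adjoints[:, 0]))
        assert np.max(np.abs(g[interior])) <= 10 * donanemab_cfg.tol * scale

    def test_optimal_beats_extreme_constant_controls(self, slow_params,
                                                     donanemab_cfg):
        sol = forward_backward_sweep(slow_params, donanemab_cfg)
        y1 = simulate(slow_params, 50, 60, step=donanemab_cfg.step).states[-1]
        for const in (0.0, donanemab_cfg.u_max):
            u = np.full_like(sol.u, const)
            traj = integrate_grid(y1, 60, 61.5, donanemab_cfg.step,
                                  slow_params, u)
            assert sol.objective <= objective(traj, u, donanemab_cfg) + 1e-9

    def test_treatment_reduces_terminal_amyloid(self, slow_params,
                                                donanemab_cfg):
        sol = forward_backward_sweep(slow_params, donanemab_cfg)
        untreated = simulate(slow_params, 50, 61.5, step=donanemab_cfg.step)
        assert sol.u.max() > 0
        assert sol.states.Abeta[-1] < untreated.Abeta[-1]

    def test_gradient_matches_finite_differences(self, slow_params):
        """Central differences of the discrete objective against the
        adjoint-based Hamiltonian gradient on a smooth interior control."""
        cfg = OCConfig(u_max=get_drug("donanemab").u_max_per_year,
                       T1=60.0, T2=61.5, step=0.005)
        y1 = simulate(slow_params, 50, cfg.T1, step=cfg.step).states[-1]
        n = round((cfg.T2 - cfg.T1) / cfg.step)
        u = np.full(n + 1, 0.3 * cfg.u_max)
        traj = integrate_grid(y1, cfg.T1, cfg.T2, cfg.step, slow_params, u)
        adj = solve_adjoint(traj, u, slow_params, cfg)
        g = control_gradient(traj, adj, u, cfg)

        def J(u_nodes):
            tr = integrate_grid(y1, cfg.T1, cfg.T2, cfg.step, slow_params,
                                u_nodes)
            return objective(tr, u_nodes, cfg)

        for k in (30, 150, 290):
            up, um = u.copy(), u.copy()
            up[k] += 1e-4
            um[k] -= 1e-4
            fd = (J(up) - J(um)) / 2e-4
            assert abs(fd - g[k] * cfg.step) / abs(fd) < 1e-3
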