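"""Pontryagin/Riccati solve: closed-form, ansatz and cross-mode oracles."""

import dataclasses
import math

import numpy as np
import pytest

from fibrocontrol import (CostWeights, TimeGrid, assemble_system,
                          build_operators, closed_loop_solve,
                          integrate_euler, riccati_backward,
                          synthesize_controls)
from fibrocontrol.control import RiccatiPath


def zero_control_system(sys):
    """Copy of the system with the control vectors removed (B = 0)."""
    n = sys.n
    return dataclasses.replace(sys, B_T=np.zeros(n), B_G=np.zeros(n),
                               b_T=0.0, b_G=0.0)


def uniform_ic(sys):
    return sys.params.m0 * np.ones(sys.n)


class TestRiccatiSweep:
    def test_terminal_conditions(self, small_system):
        grid = TimeGrid(0.0, 350.0, 500)
        path = riccati_backward(small_system, grid)
        assert path.p[-1] == 0.0 and path.g[-1] == 0.0
        assert np.all(path.p >= 0)

    def test_linear_limit_closed_form(self, small_system):
        """With B = 0 the Riccati equation is linear and
        p(t) = (1 - exp(2a(t - tf))) / (-2a); Euler converges at first
        order (error halves as the backward step count doubles)."""
        s = zero_control_system(small_system)
        d_m = s.params.d_m
        p_exact = (1.0 - math.exp(-2 * d_m * 350.0)) / (2 * d_m)
        assert p_exact == pytest.approx(30.12, abs=0.01)
        errs = []
        for steps in (2000, 4000, 8000):
            path = riccati_backward(s, TimeGrid(0.0, 350.0, steps))
            errs.append(abs(path.p[0] - p_exact))
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.05)
        assert errs[1] / errs[2] == pytest.approx(2.0, rel=0.05)

    def test_matrix_terminal_and_symmetry(self, params):
        ops = build_operators(params, 2)
        s = assemble_system(params, ops)
        grid = TimeGrid(0.0, 350.0, 800)
        path = riccati_backward(s, grid, mode="matrix")
        assert np.all(path.P[-1] == 0.0) and np.all(path.s[-1] == 0.0)
        P0 = path.P[0]
        np.testing.assert_allclose(P0, P0.T, atol=1e-12)
        assert np.linalg.eigvalsh(P0).min() >= -1e-10

    def test_matrix_ansatz_oracle(self, params):
        """With diffusion off (D_m = 0) the matrix flow preserves the
        alpha I + beta 11^T form; alpha and beta obey a closed 2-ODE
        system solved here independently."""
        p0 = dataclasses.replace(params, D_m=0.0)
        ops = build_operators(p0, 2)
        s = assemble_system(p0, ops)
        n = s.n
        grid = TimeGrid(0.0, 350.0, 2000)
        path = riccati_backward(s, grid, mode="matrix")

        a = s.a_s
        B2 = s.b_T**2 + s.b_G**2
        q_node = 1.0 / n        # mean-square weighting: Q = I/n
        alpha = np.zeros(grid.n_steps + 1)
        beta = np.zeros(grid.n_steps + 1)
        dt = grid.dt
        for k in range(grid.n_steps, 0, -1):
            al, be = alpha[k], beta[k]
            adot = -(2 * a * al + q_node)
            bdot = -(2 * a * be - B2 * (al + n * be) ** 2)
            alpha[k - 1] = al - dt * adot
            beta[k - 1] = be - dt * bdot
        expect0 = alpha[0] * np.eye(n) + beta[0] * np.ones((n, n))
        np.testing.assert_allclose(path.P[0], expect0,
                                   atol=1e-8 * abs(alpha[0]))

    def test_unknown_mode_rejected(self, small_system):
        with pytest.raises(ValueError):
            riccati_backward(small_system, TimeGrid(0.0, 1.0, 1),
                             mode="nonsense")


class TestFeedbackSynthesis:
    def test_zero_path_zero_controls(self, small_system):
        grid = TimeGrid(0.0, 350.0, 10)
        path = riccati_backward(small_system, grid)
        eta_T, eta_G, lam = synthesize_controls(
            path, uniform_ic(small_system), small_system,
            CostWeights(), k=grid.n_steps)
        assert eta_T == 0.0 and eta_G == 0.0 and lam == 0.0

    def test_control_ratio_fixed_by_saturations(self, small_system):
        # both controls are proportional to the same costate aggregate
        grid = TimeGrid(0.0, 350.0, 400)
        path = riccati_backward(small_system, grid)
        sol = closed_loop_solve(small_system, path, uniform_ic(small_system),
                                grid)
        ratio = small_system.b_T / small_system.b_G
        np.testing.assert_allclose(sol.eta_T[:-1], ratio * sol.eta_G[:-1],
                                   rtol=1e-12)

    def test_stationarity_residual(self, params):
        """dH/d eta = r eta + B^T lambda = 0 along the stored solution,
        reconstructed independently from the stored p, g and state."""
        for mode, N in (("scalar", 4), ("matrix", 2)):
            ops = build_operators(params, N)
            s = assemble_system(params, ops)
            grid = TimeGrid(0.0, 350.0, 500)
            path = riccati_backward(s, grid, mode=mode)
            sol = closed_loop_solve(s, path, uniform_ic(s), grid)
            for k in (0, 100, 250, 500):
                m_bar = sol.state_mean[k]
                if mode == "scalar":
                    lam = path.p[k] * m_bar + s.c * path.g[k]
                    res_T = sol.eta_T[k] + s.b_T * lam
                    res_G = sol.eta_G[k] + s.b_G * lam
                else:
                    lam_vec = path.P[k] @ (m_bar * np.ones(s.n)) + path.s[k]
                    res_T = sol.eta_T[k] + s.B_T @ lam_vec
                    res_G = sol.eta_G[k] + s.B_G @ lam_vec
                assert abs(res_T) <= 1e-10 and abs(res_G) <= 1e-10

    def test_hamiltonian_convexity_weights(self):
        # d2H/d eta2 are the control weights; they must be positive
        with pytest.raises(ValueError):
            CostWeights(r_T=0.0)
        with pytest.raises(ValueError):
            CostWeights(r_G=-1.0)


class TestClosedLoop:
    def test_zero_path_reduces_to_uncontrolled(self, small_system):
        grid = TimeGrid(0.0, 350.0, 300)
        zero = RiccatiPath(mode="scalar", times=grid.times,
                           weights=CostWeights(),
                           p=np.zeros(grid.n_steps + 1),
                           g=np.zeros(grid.n_steps + 1))
        sol = closed_loop_solve(small_system, zero,
                                uniform_ic(small_system), grid)
        ref = integrate_euler(small_system, uniform_ic(small_system), grid)
        np.testing.assert_array_equal(sol.state_center, ref.center_series)

    def test_uniformity_and_finiteness(self, small_system):
        grid = TimeGrid(0.0, 350.0, 2000)
        path = riccati_backward(small_system, grid)
        sol = closed_loop_solve(small_system, path,
                                uniform_ic(small_system), grid)
        assert sol.uniformity_defect <= 1e-12
        assert math.isfinite(sol.objective) and sol.objective >= 0

    def test_scalar_matrix_equivalence(self, params):
        """The two solve modes must agree on uniform problems (the matrix
        aggregates 1^T P 1, 1^T s follow the scalar flows exactly)."""
        for N in (2, 4):
            ops = build_operators(params, N)
            s = assemble_system(params, ops)
            grid = TimeGrid(0.0, 350.0, 2000)
            ic = uniform_ic(s)
            sols = {}
            for mode in ("scalar", "matrix"):
                path = riccati_backward(s, grid, mode=mode)
                sols[mode] = closed_loop_solve(s, path, ic, grid)
            diff = np.abs(sols["scalar"].state_center
                          - sols["matrix"].state_center)
            assert diff.max() <= 1e-6 * np.abs(
                sols["scalar"].state_center).max()

    def test_costate_ode_residual_first_order(self, small_system):
        """lambda = p m + c g satisfies d lambda/dt = -q m - a lambda
        identically for exact (p, g, m); on the stored Euler series the
        centered-difference residual is O(dt) and must halve with dt."""
        res = {}
        for steps in (10000, 20000):
            grid = TimeGrid(0.0, 350.0, steps)
            path = riccati_backward(small_system, grid)
            sol = closed_loop_solve(small_system, path,
                                    uniform_ic(small_system), grid)
            lam = sol.costate
            dt = grid.dt
            dlam = (lam[2:] - lam[:-2]) / (2 * dt)
            rhs = -sol.state_mean[1:-1] - small_system.a_s * lam[1:-1]
            res[steps] = np.max(np.abs(dlam - rhs)) / np.abs(lam).max()
        assert res[20000] <= 1e-5
        assert res[10000] / res[20000] == pytest.approx(2.0, rel=0.15)

    def test_optimal_cost_beats_constant_policies(self, small_system):
        """J(optimal) <= J(eta=0) and J(eta=(1,1)) under the same weights."""
        s = small_system
        grid = TimeGrid(0.0, 350.0, 2000)
        path = riccati_backward(s, grid)
        sol = closed_loop_solve(s, path, uniform_ic(s), grid)

        def const_policy_cost(eta):
            tr = integrate_euler(s, uniform_ic(s), grid, eta_T=eta,
                                 eta_G=eta)
            # same running cost as the solver: mean-square state + controls
            run = 0.5 * (tr.center_series**2 + 2 * eta**2)
            return float(np.trapezoid(run, dx=grid.dt))

        assert sol.objective <= const_policy_cost(0.0)
        assert sol.objective <= const_policy_cost(1.0)

    def test_clamp_keeps_controls_in_unit_interval(self, params):
        # exaggerate the state weight so the raw controls exceed 1
        ops = build_operators(params, 2)
        s = assemble_system(params, ops)
        grid = TimeGrid(0.0, 350.0, 2000)
        w = CostWeights(q_m=1e7)
        path = riccati_backward(s, grid, w)
        raw = closed_loop_solve(s, path, uniform_ic(s), grid)
        clamped = closed_loop_solve(s, path, uniform_ic(s), grid, clamp=True)
        assert raw.eta_G.max() > 1.0
        assert clamped.eta_G.max() <= 1.0 and clamped.eta_G.min() >= 0.0
        assert clamped.clamped and not raw.clamped

    def test_strong_state_weight_drives_density_down(self, small_system):
        # regulator sanity: with a heavy state penalty the closed loop
        # suppresses the density well below the uncontrolled plateau
        s = small_system
        grid = TimeGrid(0.0, 350.0, 2000)
        path = riccati_backward(s, grid, CostWeights(q_m=1e7))
        sol = closed_loop_solve(s, path, uniform_ic(s), grid)
        uncontrolled = integrate_euler(s, uniform_ic(s), grid)
        assert sol.state_center[1000] < 0.1 * uncontrolled.center_series[1000]
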