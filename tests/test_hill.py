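import numpy as np
import pytest

from oscnet.core import ACTIVATION, REPRESSION
from oscnet.hill import (FitHyperparams, HillParams, default_bounds,
                         fd_hessian, fit_edge_model, hill_f, hill_rhs,
                         laplace_log_evidence, mse_loss, predict_target)


PARAMS = HillParams(alpha=2.0, beta=1.0, gamma=0.3, k=1.5, n_hill=4.0)


class TestHillRhs:
    def test_half_max_identity(self):
        f = hill_f(PARAMS.k, ACTIVATION, PARAMS.alpha, PARAMS.k, PARAMS.n_hill)
        assert f == pytest.approx(PARAMS.alpha / 2)

    def test_limits_at_zero_regulator(self):
        assert hill_f(0.0, REPRESSION, 2.0, 1.5, 4.0) == pytest.approx(2.0)
        assert hill_f(0.0, ACTIVATION, 2.0, 1.5, 4.0) == pytest.approx(0.0)

    def test_activation_plus_repression_equals_alpha(self, rng):
        for H in rng.uniform(0, 5, size=10):
            total = (hill_f(H, ACTIVATION, 2.0, 1.5, 4.0)
                     + hill_f(H, REPRESSION, 2.0, 1.5, 4.0))
            assert total == pytest.approx(2.0)

    def test_rhs_composition(self):
        got = hill_rhs(1.0, PARAMS.k, ACTIVATION, PARAMS)
        assert got == pytest.approx(PARAMS.gamma - PARAMS.beta * 1.0
                                    + PARAMS.alpha / 2)


class TestPredictTarget:
    times = np.linspace(0, 6, 25)

    def test_alpha_zero_matches_exponential_relaxation(self):
        p = HillParams(0.0, 0.8, 0.4, 1.0, 2.0)
        reg = np.ones_like(self.times)
        pred = predict_target(reg, self.times, ACTIVATION, p, 3.0)
        expected = 0.5 + (3.0 - 0.5) * np.exp(-0.8 * self.times)
        assert np.allclose(pred, expected, atol=1e-6)

    def test_constant_regulator_closed_form(self):
        p = PARAMS
        hbar = 2.2
        reg = np.full_like(self.times, hbar)
        eff = p.gamma + hill_f(hbar, REPRESSION, p.alpha, p.k, p.n_hill)
        expected = eff / p.beta + (1.0 - eff / p.beta) * np.exp(-p.beta * self.times)
        pred = predict_target(reg, self.times, REPRESSION, p, 1.0)
        assert np.allclose(pred, expected, atol=1e-6)

    def test_step_halving_convergence(self, oscillating_pair):
        reg = oscillating_pair.trace("R")
        t = oscillating_pair.times
        a = predict_target(reg, t, ACTIVATION, PARAMS, 1.0, substeps=8)
        b = predict_target(reg, t, ACTIVATION, PARAMS, 1.0, substeps=16)
        assert np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-9)) < 1e-6


class TestFit:
    def test_recovers_self_consistent_target(self, oscillating_pair, rng):
        reg = oscillating_pair.trace("R")
        t = oscillating_pair.times
        truth = HillParams(1.6, 0.9, 0.2, 1.4, 3.0)
        target = predict_target(reg, t, ACTIVATION, truth, 1.0)
        _, loss = fit_edge_model(target, reg, t, ACTIVATION,
                                 FitHyperparams(n_iterations=10), rng)
        assert loss <= 1e-6 * np.var(target)

    def test_alpha_only_fit_matches_grid_search(self, oscillating_pair):
        reg = oscillating_pair.trace("R")
        t = oscillating_pair.times
        fixed = HillParams(1.234, 0.9, 0.2, 1.4, 3.0)
        target = predict_target(reg, t, ACTIVATION, fixed, 1.0)

        def loss_of_alpha(a):
            p = HillParams(a, fixed.beta, fixed.gamma, fixed.k, fixed.n_hill)
            return mse_loss(target, predict_target(reg, t, ACTIVATION, p, 1.0))

        grid = np.linspace(0.0, 3.0, 401)
        best = grid[int(np.argmin([loss_of_alpha(a) for a in grid]))]
        assert best == pytest.approx(1.234, abs=0.01)

    def test_fixed_seed_is_bit_deterministic(self, oscillating_pair):
        reg = oscillating_pair.trace("R")
        tgt = oscillating_pair.trace("T")
        t = oscillating_pair.times
        h = FitHyperparams(n_iterations=3)
        o1, l1 = fit_edge_model(tgt, reg, t, REPRESSION, h,
                                np.random.default_rng(42))
        o2, l2 = fit_edge_model(tgt, reg, t, REPRESSION, h,
                                np.random.default_rng(42))
        assert o1 == o2 and l1 == l2

    def test_bounds_track_data_scales(self):
        b = default_bounds(np.array([0.5, 4.0]), np.array([0.2, 2.0]))
        assert b[3] == (0.2, 2.0)       # k within regulator range
        assert b[4] == (1.0, 10.0)      # Hill exponent


class TestLaplaceEvidence:
    def test_one_dimensional_gaussian_integral(self):
        # E(x) = x^2/2 -> integral sqrt(2 pi), log evidence = log(2pi)/2
        assert laplace_log_evidence(0.0, np.array([[1.0]]), dim=1) == \
            pytest.approx(0.5 * np.log(2 * np.pi))

    def test_matches_quadrature_on_quadratic_2d(self):
        H = np.array([[2.0, 0.4], [0.4, 1.0]])

        def energy(v):
            return 0.5 * v @ H @ v + 0.7

        from scipy.integrate import dblquad
        val, _ = dblquad(lambda y, x: np.exp(-energy(np.array([x, y]))),
                         -8, 8, -8, 8)
        approx = laplace_log_evidence(0.7, H, dim=2)
        assert approx == pytest.approx(np.log(val), abs=0.01)

    def test_hessian_inflation_penalty(self):
        H = np.array([[2.0, 0.4], [0.4, 1.0]])
        drop = (laplace_log_evidence(0.0, H, 2)
                - laplace_log_evidence(0.0, 4.0 * H, 2))
        assert drop == pytest.approx(0.5 * 2 * np.log(4.0))

    def test_singular_hessian_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="singular"):
            ev = laplace_log_evidence(1.5, np.array([[np.nan, 0], [0, 1.0]]), 2)
        assert ev == -1.5

    def test_fd_hessian_on_quadratic(self):
        A = np.array([[3.0, 1.0], [1.0, 2.0]])
        H = fd_hessian(lambda v: 0.5 * v @ A @ v, np.array([1.0, 1.0]))
        assert np.allclose(H, A, atol=1e-4)
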