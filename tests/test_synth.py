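import numpy as np
import pytest

from oscnet.synth import (GROUND_TRUTH_PARAMS, HILL_EXPONENT, default_t_grid,
                          fold_change_check, simulate_ground_truth,
                          simulate_reduced, spurious_wave)
from oscnet.timeseries import TimeSeriesSet


class TestParameterTable:
    def test_stored_basal_rate_spot_value(self):
        assert GROUND_TRUTH_PARAMS[("B", "F")][0][0] == 0.1071294686

    def test_ten_regulated_pairs_exponent_five(self):
        assert len(GROUND_TRUTH_PARAMS) == 10
        assert HILL_EXPONENT == 5.0
        for cols in GROUND_TRUTH_PARAMS.values():
            assert len(cols) == 3
            assert all(v > 0 for col in cols for v in col)


class TestSimulation:
    def test_solver_step_convergence(self):
        t = default_t_grid(20.0, 0.1)
        coarse = simulate_ground_truth(1, t, rtol=1e-9, atol=1e-11)
        fine = simulate_ground_truth(1, t, rtol=1e-11, atol=1e-13)
        rel = np.max(np.abs(coarse.values - fine.values)
                     / np.maximum(np.abs(fine.values), 1e-8))
        assert rel < 1e-6

    def test_omega_zero_decouples_to_basal_fixed_point(self, monkeypatch):
        # with all regulation amplitudes off, C must relax to the product /
        # sum of basal rates and nothing oscillates
        import oscnet.synth as synth
        zeroed = {pair: tuple((g, 0.0, th) for (g, _o, th) in cols)
                  for pair, cols in GROUND_TRUTH_PARAMS.items()}
        monkeypatch.setattr(synth, "GROUND_TRUTH_PARAMS", zeroed)
        t = default_t_grid(40.0, 0.1)
        ts = synth.simulate_ground_truth(1, t)
        p = {k: v[0] for k, v in zeroed.items()}
        expected_c = ((p[("A", "C")][0] + p[("E", "C")][0]) * p[("D", "C")][0])
        tail = ts.values[:, t > 30]
        assert np.allclose(tail[2], expected_c, rtol=1e-4)
        assert np.all(tail.max(axis=1) - tail.min(axis=1) < 1e-4)

    def test_trajectories_positive_and_bounded(self):
        for col in (1, 2, 3):
            ts = simulate_ground_truth(col, default_t_grid(40.0, 0.05))
            assert np.all(ts.values > 0)
            assert np.all(ts.values < 50)

    def test_bad_column_rejected(self):
        with pytest.raises(ValueError):
            simulate_ground_truth(4)


class TestReduction:
    def test_removing_node_d_kills_oscillation_for_column_1(self):
        ts = simulate_reduced(1)
        t = ts.times
        early = ts.values[:, t < 20]        # decaying onset
        late = ts.values[:, t >= 60]        # settled tail
        amp_late = late.max(axis=1) - late.min(axis=1)
        amp_early = early.max(axis=1) - early.min(axis=1)
        # decay to equilibrium: late amplitude a small fraction of early
        assert np.all(amp_late <= 0.1 * np.maximum(amp_early, 1e-12))

    def test_column_3_oscillates_without_node_d(self):
        ts = simulate_reduced(3)
        late = ts.values[:, ts.times >= 60]
        assert np.all(late.max(axis=1) - late.min(axis=1) > 0.1)

    def test_adding_back_d_terms_recovers_full_system(self):
        # integrating the reduced equations augmented with the D equation and
        # C's D-dependent factor must reproduce the six-variable trajectories
        from scipy.integrate import solve_ivp
        col = 1
        p = {pair: vals[col - 1] for pair, vals in GROUND_TRUTH_PARAMS.items()}
        n = HILL_EXPONENT

        def act(x, th):
            return x ** n / (x ** n + th ** n)

        def rep(x, th):
            return th ** n / (x ** n + th ** n)

        def term(pair, x, kind):
            g, om, th = p[pair]
            return g + om * (act(x, th) if kind == "a" else rep(x, th))

        def rhs(_t, y):
            A, B, C, D, E, F = y
            return [
                -A + term(("F", "A"), F, "a"),
                -B + term(("C", "B"), C, "a"),
                -C + (term(("A", "C"), A, "a") + term(("E", "C"), E, "a"))
                     * term(("D", "C"), D, "r"),
                -D + term(("A", "D"), A, "r") * term(("E", "D"), E, "r"),
                -E + term(("B", "E"), B, "r") * term(("F", "E"), F, "a"),
                -F + term(("B", "F"), B, "r"),
            ]

        t = default_t_grid(20.0, 0.1)
        ref = solve_ivp(rhs, (0, 20), np.ones(6), t_eval=t, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        ts = simulate_ground_truth(col, t)
        assert np.allclose(ts.values, ref.y, rtol=1e-5, atol=1e-7)


class TestSpuriousWave:
    def test_range_and_mean(self):
        omega = 2 * np.pi
        t = np.linspace(0, 3, 3001)  # three whole periods
        w = spurious_wave(t, omega)
        assert w.min() == pytest.approx(0.0, abs=1e-5)
        assert w.max() == pytest.approx(4.0, abs=1e-5)
        assert np.trapezoid(w, t) / 3 == pytest.approx(2.0, abs=1e-3)

    def test_period_by_autocorrelation(self):
        omega = 3.0
        t = np.arange(0, 50, 0.01)
        w = spurious_wave(t, omega) - 2.0
        ac = np.correlate(w, w, mode="full")[w.size - 1:]
        # first local maximum after lag zero sits at one period
        d = np.diff(ac)
        rising = np.nonzero((d[:-1] < 0) & (d[1:] >= 0))[0]
        first_peak = None
        for i in rising:
            j = i + 1
            while j < ac.size - 1 and ac[j + 1] >= ac[j]:
                j += 1
            first_peak = j
            break
        assert first_peak is not None
        assert t[first_peak] == pytest.approx(2 * np.pi / omega, rel=1e-2)


class TestFoldChange:
    def test_constant_trace_ratio_one(self):
        ts = TimeSeriesSet(["g"], [0, 1, 2, 3], [[2.0, 2.0, 2.0, 2.0]])
        assert fold_change_check(ts, 0.25) == pytest.approx(1.0)

    def test_known_ratio(self):
        ts = TimeSeriesSet(["g"], np.arange(8.0),
                           [[1.0, 4.0, 1.0, 4.0, 1.0, 4.0, 1.0, 4.0]])
        assert fold_change_check(ts, 0.0) == pytest.approx(4.0)

    @pytest.mark.parametrize("col", [1, 2, 3])
    def test_benchmark_attains_four_fold_change(self, col):
        assert fold_change_check(simulate_ground_truth(col)) >= 4.0
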