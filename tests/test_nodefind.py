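import itertools
import math

import numpy as np
import pytest

from oscnet.nodefind import (NodeScore, cosine_templates, dlxjtk_score,
                             empirical_p_reg, exact_null_s, jtk_p_per,
                             kendall_s, rank_nodes, regulator_score)
from oscnet.timeseries import TimeSeriesSet


class TestRegulatorScore:
    def test_constant_trace_scores_zero(self):
        assert regulator_score(np.full(7, 3.3)) == 0.0

    def test_two_point_worked_value(self):
        # log10 of (10, 100)/55 deviates +-0.5 about its mean
        assert regulator_score(np.array([10.0, 100.0])) == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        x = rng.uniform(0.5, 5.0, size=20)
        assert regulator_score(3.7 * x) == pytest.approx(regulator_score(x))

    def test_nonpositive_rejected_with_pseudocount_hint(self):
        with pytest.raises(ValueError, match="pseudo_count"):
            regulator_score(np.array([1.0, 0.0, 2.0]))
        assert regulator_score(np.array([1.0, 0.0, 2.0]), pseudo_count=1.0) > 0


class TestEmpiricalPReg:
    def test_degenerate_identical_constant_curves(self, rng):
        ts = TimeSeriesSet(["a", "b"], [0, 1, 2],
                           [[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        # every random curve scores 0, never strictly exceeding 0
        assert empirical_p_reg("a", ts, 50, rng) == 0.0

    def test_matches_exhaustive_enumeration(self):
        # 2 curves x 3 times: only 8 possible random curves, uniformly likely
        ts = TimeSeriesSet(["a", "b"], [0, 1, 2],
                           [[1.0, 2.0, 4.0], [4.0, 2.0, 1.0]])
        target = regulator_score(ts.trace("a"))
        vals = ts.values
        exceed = mass = 0
        for combo in itertools.product(range(2), repeat=3):
            curve = np.array([vals[c, t] for t, c in enumerate(combo)])
            mass += 1
            if regulator_score(curve) > target:
                exceed += 1
        expected = exceed / mass
        draws = [empirical_p_reg("a", ts, 400, np.random.default_rng(s))
                 for s in range(8)]
        assert np.mean(draws) == pytest.approx(expected, abs=0.05)

    def test_invariant_to_gene_relabeling(self, toy_dataset):
        relabeled = TimeSeriesSet(["x", "y", "z"], toy_dataset.times,
                                  toy_dataset.values.copy(), "r")
        p1 = empirical_p_reg("g1", toy_dataset, 300, np.random.default_rng(7))
        p2 = empirical_p_reg("x", relabeled, 300, np.random.default_rng(7))
        assert p1 == p2


class TestExactNull:
    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_untied_recursion_equals_enumeration(self, n, rng):
        """Dual route: inversion-count recursion vs exhaustive permutations."""
        x = rng.permutation(np.arange(n, dtype=float) + 1)
        y = np.arange(n, dtype=float)
        from oscnet.nodefind import _null_by_enumeration, _null_untied
        brute = _null_by_enumeration(x, y)
        fast = _null_untied(n)
        assert set(brute) == set(fast)
        for s in brute:
            assert brute[s] == pytest.approx(fast[s], abs=1e-12)

    def test_tied_template_null_sums_to_one(self):
        null = exact_null_s((1.0, 2.0, 3.0, 4.0), (0.0, 1.0, 1.0, 0.0))
        assert sum(null.values()) == pytest.approx(1.0)

    def test_null_probabilities_match_brute_force_tail(self, rng):
        x = tuple(rng.uniform(0, 1, size=6))
        y = tuple(np.cos(np.linspace(0, 2 * np.pi, 6)))
        null = exact_null_s(x, y)
        s_obs = kendall_s(np.array(x), np.array(y))
        tail = sum(p for s, p in null.items() if s >= s_obs)
        # independent brute force
        count = total = 0
        for perm in itertools.permutations(x):
            total += 1
            if kendall_s(np.array(perm), np.array(y)) >= s_obs:
                count += 1
        assert tail == pytest.approx(count / total, abs=1e-12)


class TestJtkPPer:
    def test_trace_equal_to_template_attains_minimal_p(self):
        times = np.arange(8.0)
        templates = cosine_templates(times, [8.0])
        trace = templates[0] + 2.0
        p = jtk_p_per(trace, times, [8.0])
        null = exact_null_s(tuple(trace), tuple(templates[0]))
        smax = max(null)
        expected = sum(v for s, v in null.items() if s >= smax) * len(templates)
        assert p == pytest.approx(expected)

    def test_reversed_trace_matches_antiphase_equally(self):
        times = np.arange(6.0)
        trace = np.cos(2 * np.pi * times / 6.0) + 2.0
        assert jtk_p_per(trace, times, [6.0]) == pytest.approx(
            jtk_p_per(trace[::-1], times, [6.0]))

    def test_constant_trace_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert jtk_p_per(np.ones(5), np.arange(5.0), [4.0]) == 1.0


class TestCombinedScore:
    def test_plug_in_at_knee(self):
        assert dlxjtk_score(0.001, 0.001) == pytest.approx(4e-6)

    def test_annihilation_at_zero_p_reg(self):
        assert dlxjtk_score(0.0, 0.7) == 0.0

    def test_strictly_increasing_in_p_reg(self):
        import sympy
        p, q = sympy.symbols("p q", positive=True)
        expr = p * q * (1 + (p / sympy.Rational(1, 1000)) ** 2) \
                     * (1 + (q / sympy.Rational(1, 1000)) ** 2)
        deriv = sympy.diff(expr, p)
        # derivative q(1 + 3e6 p^2)(1 + 1e6 q^2) is positive for q > 0
        assert sympy.simplify(deriv) == sympy.nsimplify(
            q * (1 + 3_000_000 * p ** 2) * (1 + 1_000_000 * q ** 2))

    def test_node_ranking_tsv_carries_both_p_values(self, tmp_path):
        from oscnet.nodefind import write_node_ranking
        scores = [NodeScore("a", 0.01, 0.02, dlxjtk_score(0.01, 0.02), 10),
                  NodeScore("b", 0.5, 0.5, dlxjtk_score(0.5, 0.5), 10)]
        table = rank_nodes(scores)
        p = tmp_path / "nodes.tsv"
        write_node_ranking(table, scores, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "gene\tp_reg\tp_per\tdlxjtk\trank"
        assert lines[1].startswith("a\t0.01\t0.02")

    def test_rank_nodes_orders_and_truncates(self):
        scores = [NodeScore("a", 0.001, 0.001, 4e-6, 10),
                  NodeScore("b", 1.0, 1.0, dlxjtk_score(1.0, 1.0), 10),
                  NodeScore("c", 0.01, 0.01, dlxjtk_score(0.01, 0.01), 10)]
        table = rank_nodes(scores)
        assert table.keys == ["a", "c", "b"]
        assert rank_nodes(scores, top_k=1).keys == ["a"]
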