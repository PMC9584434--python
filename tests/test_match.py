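import itertools

import numpy as np
import pytest

from oscnet.events import MAX, MIN, DataGraph, ExtremumEvent, build_data_graph
from oscnet.match import (UnsupportedFeatureError, cycle_event_sequence,
                          pattern_match, score_network)
from oscnet.netspec import parse_network
from oscnet.regions import enumerate_parameter_regions
from oscnet.stg import build_stg, morse_graph


def automaton_of(text):
    net = parse_network(text)
    region = enumerate_parameter_regions(net, True)[0]
    stg = build_stg(net, region)
    morse = morse_graph(stg)
    comp = morse.stable_full_cycles()[0]
    return cycle_event_sequence(stg, morse, comp)


def graph_from_times(times_by_label, width=0.0):
    """Data graph from (gene, kind) -> time, optional interval half-width."""
    by_gene = {}
    for (gene, kind), t in times_by_label.items():
        by_gene.setdefault(gene, []).append(
            ExtremumEvent(gene, kind, t, t - width, t + width))
    for evs in by_gene.values():
        evs.sort(key=lambda e: e.nominal_time)
    return build_data_graph(by_gene)


def rotation_extension_oracle(word, dg):
    """Exhaustive check: some rotation of the cyclic word is a linear
    extension of the data graph's partial order."""
    labels = [e.label for e in dg.events]
    sub = [x for x in word if x in set(labels)]
    from collections import Counter
    if Counter(sub) != Counter(labels):
        return False
    label_to_event = {e.label: i for i, e in enumerate(dg.events)}
    pred = dg.predecessors_mask()
    n = len(sub)
    for r in range(n):
        rot = sub[r:] + sub[:r]
        seen = 0
        ok = True
        for lab in rot:
            ev = label_to_event[lab]
            if pred[ev] & ~seen:
                ok = False
                break
            seen |= 1 << ev
        if ok:
            return True
    return False


class TestCycleEventSequence:
    def test_negative_loop_word(self):
        auto = automaton_of("A : ~B\nB : A\n")
        word = auto.event_word_if_simple_cycle()
        # a rotation of max_A, max_B, min_A, min_B
        joined = word + word
        start = joined.index(("A", MAX))
        assert joined[start:start + 4] == [("A", MAX), ("B", MAX),
                                           ("A", MIN), ("B", MIN)]

    def test_word_has_equal_max_min_counts_per_gene(self):
        auto = automaton_of("A : ~C\nB : ~A\nC : ~B\n")
        word = auto.event_word_if_simple_cycle()
        for g in "ABC":
            assert word.count((g, MAX)) == word.count((g, MIN)) == 1

    def test_fixed_point_component_rejected(self):
        net = parse_network("A : B\nB : A\n")
        region = enumerate_parameter_regions(net, True)[0]
        stg = build_stg(net, region)
        morse = morse_graph(stg)
        with pytest.raises(ValueError, match="not a cycle"):
            cycle_event_sequence(stg, morse, morse.stable[0])


class TestPatternMatch:
    def test_empty_data_graph_matches_vacuously(self):
        auto = automaton_of("A : ~B\nB : A\n")
        assert pattern_match(auto, DataGraph([], set()))

    def test_matches_own_cyclic_word(self):
        auto = automaton_of("A : ~B\nB : A\n")
        dg = graph_from_times({("A", MAX): 0.0, ("B", MAX): 1.0,
                               ("A", MIN): 2.0, ("B", MIN): 3.0})
        assert pattern_match(auto, dg)

    def test_rejects_swapped_maxima_order(self):
        auto = automaton_of("A : ~B\nB : A\n")
        dg = graph_from_times({("B", MAX): 0.0, ("A", MAX): 1.0,
                               ("A", MIN): 2.0, ("B", MIN): 3.0})
        assert not pattern_match(auto, dg)

    def test_overlapping_intervals_relax_the_order(self):
        auto = automaton_of("A : ~B\nB : A\n")
        # wide intervals make the two maxima incomparable, restoring a match
        dg = graph_from_times({("B", MAX): 0.0, ("A", MAX): 1.0,
                               ("A", MIN): 5.0, ("B", MIN): 6.0}, width=1.5)
        assert pattern_match(auto, dg)

    def test_genes_absent_from_network_are_projected_out(self):
        auto = automaton_of("A : ~B\nB : A\n")
        dg = graph_from_times({("A", MAX): 0.0, ("Z", MAX): 0.5,
                               ("B", MAX): 1.0, ("A", MIN): 2.0,
                               ("Z", MIN): 2.5, ("B", MIN): 3.0})
        assert pattern_match(auto, dg)

    def test_self_repression_rejected(self):
        net = parse_network("A : (~A)(B)\nB : A\n")
        region = enumerate_parameter_regions(net, essential_only=False)[0]
        stg = build_stg(net, region)
        morse = morse_graph(stg)
        from oscnet.match import CycleAutomaton
        auto = CycleAutomaton(net, np.arange(stg.n_states),
                              list(zip(stg.edges_from.tolist(),
                                       stg.edges_to.tolist())),
                              stg.directions())
        with pytest.raises(UnsupportedFeatureError):
            pattern_match(auto, DataGraph([], set()))

    @pytest.mark.parametrize("net_text", ["A : ~B\nB : A\n",
                                          "A : ~C\nB : ~A\nC : ~B\n"])
    def test_agrees_with_rotation_extension_oracle(self, net_text, rng):
        """Exhaustive rotations x linear-extensions check on <= 8 events."""
        auto = automaton_of(net_text)
        word = auto.event_word_if_simple_cycle()
        genes = sorted({g for g, _ in word})
        for trial in range(60):
            times = {}
            for g in genes:
                t_max = rng.uniform(0, 10)
                t_min = rng.uniform(0, 10)
                while abs(t_max - t_min) < 1e-6:
                    t_min = rng.uniform(0, 10)
                times[(g, MAX)] = t_max
                times[(g, MIN)] = t_min
            width = float(rng.choice([0.0, 0.5, 2.0]))
            dg = graph_from_times(times, width)
            assert pattern_match(auto, dg) == rotation_extension_oracle(word, dg)


class TestSelfConsistency:
    def test_hill_repressilator_matches_its_own_cycle(self):
        """A switching-faithful oscillator's data graph matches the stable
        cycle of its generating parameter region."""
        from scipy.integrate import solve_ivp
        from oscnet.events import extract_events, estimate_period
        from oscnet.timeseries import TimeSeriesSet

        n = 10.0
        theta, gam, om = 1.0, 0.2, 1.8  # l = 0.2 < theta < 2.0 = u

        def rhs(_t, y):
            a, b, c = y
            rep = lambda x: theta ** n / (x ** n + theta ** n)
            return [-a + gam + om * rep(c),
                    -b + gam + om * rep(a),
                    -c + gam + om * rep(b)]

        t = np.arange(0, 60, 0.02)
        sol = solve_ivp(rhs, (0, 60), [1.5, 0.3, 0.9], t_eval=t,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        ts = TimeSeriesSet(["A", "B", "C"], t, sol.y, "rep")
        period = estimate_period(ts)
        by_gene = {}
        for g in ts.gene_names:
            evs = [e for e in extract_events(ts.trace(g), ts.times, 0.0, g)
                   if 40.0 <= e.nominal_time < 40.0 + period]
            by_gene[g] = evs
        dg = build_data_graph(by_gene)
        assert dg.n_events == 6
        auto = automaton_of("A : ~C\nB : ~A\nC : ~B\n")
        assert pattern_match(auto, dg)


class TestScoreNetwork:
    def test_two_node_scores_match_exhaustive_region_oracle(self):
        net = parse_network("A : ~B\nB : A\n")
        word_dg = graph_from_times({("A", MAX): 0.0, ("B", MAX): 1.0,
                                    ("A", MIN): 2.0, ("B", MIN): 3.0})
        bad_dg = graph_from_times({("B", MAX): 0.0, ("A", MAX): 1.0,
                                   ("A", MIN): 2.0, ("B", MIN): 3.0})
        scores = score_network(net, {"good": word_dg, "bad": bad_dg})
        assert scores.n_regions == 1
        assert scores.oscillation_score == 1.0
        assert scores.per_dataset_scores == {"good": 1.0, "bad": 0.0}
        assert scores.pattern_match_score == 1.0  # matched at least one
        assert scores.replicate_flags == {"good": True, "bad": False}

    def test_pattern_match_score_from_raw_datasets(self):
        import numpy as np
        from oscnet.match import pattern_match_score
        from oscnet.timeseries import TimeSeriesSet
        # anti-phase-ish sinusoids realize the negative loop's cyclic word
        t = np.arange(0, 40, 0.05)
        a = 2 + np.sin(2 * np.pi * t / 5.0)
        b = 2 + np.sin(2 * np.pi * (t - 1.25) / 5.0)
        ts = TimeSeriesSet(["A", "B"], t, np.vstack([a, b]), "d1")
        net = parse_network("A : ~B\nB : A\n")
        assert pattern_match_score(net, {"d1": ts}, epsilon=0.0) == 1.0

    def test_non_oscillating_network_scores_zero(self):
        net = parse_network("A : B\nB : A\n")
        dg = graph_from_times({("A", MAX): 0.0, ("A", MIN): 1.0})
        scores = score_network(net, {"d": dg})
        assert scores.oscillation_score == 0.0
        assert scores.pattern_match_score == 0.0
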