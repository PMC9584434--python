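"""Shared brute-force oracles for the test-suite."""

from collections import Counter

import numpy as np

from oscnet.events import ExtremumEvent, build_data_graph
from oscnet.match import cycle_event_sequence, pattern_match
from oscnet.netspec import parse_network
from oscnet.regions import enumerate_parameter_regions
from oscnet.stg import build_stg, morse_graph


def simple_cycle_automaton(text):
    net = parse_network(text)
    region = enumerate_parameter_regions(net, True)[0]
    stg = build_stg(net, region)
    morse = morse_graph(stg)
    return cycle_event_sequence(stg, morse, morse.stable_full_cycles()[0])


def rotation_extension_oracle(word, dg):
    """Some rotation of the cyclic word is a linear extension of the data
    graph's partial order (events restricted to the word's genes)."""
    labels = [e.label for e in dg.events]
    sub = [x for x in word if x in set(labels)]
    if Counter(sub) != Counter(labels):
        return False
    label_to_event = {e.label: i for i, e in enumerate(dg.events)}
    pred = dg.predecessors_mask()
    for r in range(len(sub)):
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


def match_oracle_trials(rng: np.random.Generator, n_trials: int = 25) -> None:
    """Random <=8-event instances: matcher verdict equals the exhaustive
    rotations-times-linear-extensions oracle."""
    for text in ("A : ~B\nB : A\n", "A : ~C\nB : ~A\nC : ~B\n"):
        auto = simple_cycle_automaton(text)
        word = auto.event_word_if_simple_cycle()
        genes = sorted({g for g, _ in word})
        for _ in range(n_trials):
            by_gene = {}
            for g in genes:
                t_max = float(rng.uniform(0, 10))
                t_min = float(rng.uniform(0, 10))
                while abs(t_max - t_min) < 1e-6:
                    t_min = float(rng.uniform(0, 10))
                w = float(rng.choice([0.0, 0.5, 2.0]))
                evs = [ExtremumEvent(g, "max", t_max, t_max - w, t_max + w),
                       ExtremumEvent(g, "min", t_min, t_min - w, t_min + w)]
                evs.sort(key=lambda e: e.nominal_time)
                by_gene[g] = evs
            dg = build_data_graph(by_gene)
            assert pattern_match(auto, dg) == rotation_extension_oracle(word, dg)
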