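"""Matching stable cycles of a switching model against extremum orders.

A stable full-cycle component of a state transition graph induces, along
each of its cyclic paths, a sequence of extremum events: a node switching
from increasing to decreasing emits a local maximum, the reverse switch a
local minimum (steadiness is transparent — a node may pause at a level
without forgetting its approach direction).  A network is *consistent*
with a dataset when some cyclic path emits, once per period, exactly the
dataset's events in an order compatible with the data graph's partial
order.  Matching is rotation-invariant: the cycle must close up over one
full period, but where the period starts is free.

The search runs over the product of the component (augmented with carried
direction memory) and the lattice of down-sets (order ideals) of the data
graph; completing the event set wraps the ideal back to empty, and a match
is a product cycle through a wrap transition (found via strongly connected
components).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import MAX, MIN, DataGraph
from .netspec import RegulatoryNetwork
from .regions import ParameterRegion, enumerate_parameter_regions
from .stg import MorseGraph, StateTransitionGraph, build_stg, morse_graph


class UnsupportedFeatureError(RuntimeError):
    """Raised for networks outside the matcher's scope (self-repression)."""


@dataclass
class CycleAutomaton:
    """Event-emitting automaton of one Morse component.

    ``states`` are STG state indices in the component; ``edges`` are
    ``(i, j)`` index pairs into ``states``; traversing an edge emits the
    events produced by every node whose direction switches.  Emission
    depends on carried directions, which the matcher threads through its
    product construction; ``edge_switches`` records, per edge, the nodes
    whose direction at the head state is definite.
    """

    network: RegulatoryNetwork
    states: np.ndarray                       # component member state indices
    edges: list[tuple[int, int]]             # local indices
    directions: np.ndarray                   # (n_nodes, n_local) in {-1,0,+1}

    def event_word_if_simple_cycle(self) -> list[tuple[str, str]]:
        """The cyclic event word when the component is a single cycle.

        Only defined when every state has exactly one outgoing edge.
        Useful as a readable summary and in hand-checked oracles.
        """
        succ: dict[int, int] = {}
        for i, j in self.edges:
            if i in succ:
                raise ValueError("component is not a simple cycle")
            succ[i] = j
        word: list[tuple[str, str]] = []
        n_nodes = self.directions.shape[0]
        start = 0
        order = [start]
        cur = succ[start]
        while cur != start:
            order.append(cur)
            cur = succ[cur]
        carried = [0] * n_nodes
        # one warm-up lap to initialize carried directions, then emit
        for lap in range(2):
            for k in range(len(order)):
                nxt = order[(k + 1) % len(order)]
                for v in range(n_nodes):
                    d = int(self.directions[v, nxt])
                    if d == 0:
                        continue
                    if carried[v] != 0 and d != carried[v] and lap == 1:
                        word.append((self.network.nodes[v],
                                     MAX if carried[v] > 0 else MIN))
                    carried[v] = d
        return word


def cycle_event_sequence(stg: StateTransitionGraph, morse: MorseGraph,
                         component: int) -> CycleAutomaton:
    """Searchable event structure of a cycle-annotated Morse component."""
    if morse.annotations[component] in ("fixed_point", "transient"):
        raise ValueError("component is not a cycle")
    member = np.nonzero(morse.labels == component)[0]
    local = {int(s): k for k, s in enumerate(member)}
    edges = [(local[int(a)], local[int(b)])
             for a, b in zip(stg.edges_from, stg.edges_to)
             if int(a) in local and int(b) in local]
    dirs = stg.directions()[:, member]
    return CycleAutomaton(stg.network, member, edges, dirs)


def pattern_match(automaton: CycleAutomaton, data_graph: DataGraph) -> bool:
    """True iff some cyclic path of the component realizes the data graph.

    The data graph is first projected to the network's genes; genes of the
    network with no data events are unconstrained.  An empty data graph
    matches vacuously.  Networks with self-repressing edges are rejected.
    """
    net = automaton.network
    if net.has_self_repression():
        raise UnsupportedFeatureError(
            "pattern matching is not available for self-repressing edges")
    dg = data_graph.project(set(net.nodes))
    n_events = dg.n_events
    if n_events == 0:
        return True

    pred = dg.predecessors_mask()
    full = (1 << n_events) - 1
    by_label: dict[tuple[str, str], list[int]] = {}
    for i, e in enumerate(dg.events):
        by_label.setdefault(e.label, []).append(i)

    n_nodes = len(net.nodes)
    dirs = automaton.directions
    n_local = automaton.states.size
    succ: dict[int, list[int]] = {}
    for i, j in automaton.edges:
        succ.setdefault(i, []).append(j)

    # --- seed product states: empty ideal, all direction guesses for
    # currently-steady nodes (carried directions are part of the state)
    def seed_memos(k: int):
        steady = [v for v in range(n_nodes) if dirs[v, k] == 0]
        base = [int(dirs[v, k]) for v in range(n_nodes)]
        def rec(idx, memo):
            if idx == len(steady):
                yield tuple(memo)
                return
            for d in (1, -1):
                memo[steady[idx]] = d
                yield from rec(idx + 1, memo)
        yield from rec(0, list(base))

    # --- transition: returns list of (new_memo, emitted_labels)
    def step(k_to: int, memo: tuple[int, ...]):
        emitted: list[tuple[str, str]] = []
        new = list(memo)
        for v in range(n_nodes):
            d = int(dirs[v, k_to])
            if d == 0:
                continue
            if d != memo[v]:
                emitted.append((net.nodes[v], MAX if memo[v] > 0 else MIN))
            new[v] = d
        return tuple(new), emitted

    def ideal_successors(ideal: int, emitted: list[tuple[str, str]]):
        """Ideals reachable by adding the emitted events, serialized.

        A single qualitative step abstracts a stretch of continuous time,
        so events emitted together may occur in any order; every
        poset-consistent interleaving is explored.  Completing the event
        set wraps the ideal back to empty (flagged), possibly mid-sequence.
        """
        needed = [lab for lab in emitted if lab in by_label]
        results: set[tuple[int, bool]] = set()

        def assign(cur: int, wrapped: bool, remaining: tuple):
            if not remaining:
                results.add((cur, wrapped))
                return
            for idx, lab in enumerate(remaining):
                for ev in by_label[lab]:
                    bit = 1 << ev
                    if bit & cur or (pred[ev] & ~cur):
                        continue
                    nxt = cur | bit
                    w2 = wrapped
                    if nxt == full:
                        nxt, w2 = 0, True
                    assign(nxt, w2, remaining[:idx] + remaining[idx + 1:])

        assign(ideal, False, tuple(needed))
        return results

    # --- build reachable product graph
    index: dict[tuple[int, int, tuple[int, ...]], int] = {}
    adj: list[list[int]] = []
    wrap_edges: list[tuple[int, int]] = []
    stack: list[tuple[int, int, tuple[int, ...]]] = []

    def get(node):
        if node not in index:
            index[node] = len(adj)
            adj.append([])
            stack.append(node)
        return index[node]

    for k in range(n_local):
        for memo in seed_memos(k):
            get((k, 0, memo))
    while stack:
        node = stack.pop()
        k, ideal, memo = node
        i = index[node]
        for k2 in succ.get(k, ()):
            memo2, emitted = step(k2, memo)
            for ideal2, wrapped in ideal_successors(ideal, emitted):
                j = get((k2, ideal2, memo2))
                adj[i].append(j)
                if wrapped:
                    wrap_edges.append((i, j))

    if not wrap_edges:
        return False
    comp = _scc(adj)
    return any(comp[a] == comp[b] for a, b in wrap_edges)


def _scc(adj: list[list[int]]) -> list[int]:
    """Iterative Tarjan strongly connected components."""
    n = len(adj)
    index_of = [-1] * n
    low = [0] * n
    on_stack = [False] * n
    comp = [-1] * n
    stack: list[int] = []
    counter = 0
    n_comp = 0
    for root in range(n):
        if index_of[root] != -1:
            continue
        work = [(root, 0)]
        while work:
            v, pi = work[-1]
            if pi == 0:
                index_of[v] = low[v] = counter
                counter += 1
                stack.append(v)
                on_stack[v] = True
            recurse = False
            for ei in range(pi, len(adj[v])):
                w = adj[v][ei]
                if index_of[w] == -1:
                    work[-1] = (v, ei + 1)
                    work.append((w, 0))
                    recurse = True
                    break
                elif on_stack[w]:
                    low[v] = min(low[v], index_of[w])
            if recurse:
                continue
            if low[v] == index_of[v]:
                while True:
                    w = stack.pop()
                    on_stack[w] = False
                    comp[w] = n_comp
                    if w == v:
                        break
                n_comp += 1
            work.pop()
            if work:
                u, _ = work[-1]
                low[u] = min(low[u], low[v])
    return comp


def pattern_match_score(network: RegulatoryNetwork, datasets,
                        epsilon: float = 0.0,
                        essential_only: bool = True,
                        cap: int | None = None) -> float:
    """Fraction of stably oscillating regions matching at least one dataset.

    ``datasets`` maps names to :class:`~oscnet.timeseries.TimeSeriesSet`
    objects; each is reduced to one period of extremum events at noise
    level ``epsilon`` before matching.  Defined as 0 when no region
    oscillates.
    """
    from .events import periodic_data_graph
    graphs = {name: periodic_data_graph(ts, epsilon)
              for name, ts in datasets.items()}
    return score_network(network, graphs, essential_only, cap).pattern_match_score


@dataclass
class DynamicsScores:
    """Oscillation and pattern-match scores of one network."""

    n_regions: int
    n_oscillating: int
    matches_per_dataset: dict[str, int]
    oscillation_score: float
    pattern_match_score: float
    per_dataset_scores: dict[str, float] = field(default_factory=dict)
    replicate_flags: dict[str, bool] = field(default_factory=dict)


def score_network(network: RegulatoryNetwork,
                  data_graphs: dict[str, DataGraph],
                  essential_only: bool = True,
                  cap: int | None = None,
                  regions: list[ParameterRegion] | None = None,
                  max_in_degree: int = 4) -> DynamicsScores:
    """Oscillation score and pattern-match score against one or more datasets.

    The oscillation score is the fraction of (essential) parameter regions
    whose Morse graph contains a stable full cycle.  The pattern-match
    score is the fraction of those stably-oscillating regions in which
    some stable full cycle matches at least one dataset; per-dataset
    fractions and per-dataset any-match flags are retained for the
    top-network selection rules.
    """
    if regions is None:
        regions = enumerate_parameter_regions(network, essential_only, cap,
                                              max_in_degree)
    n_osc = 0
    matched_any = 0
    per_ds = {name: 0 for name in data_graphs}
    for region in regions:
        stg = build_stg(network, region)
        morse = morse_graph(stg)
        comps = morse.stable_full_cycles()
        if not comps:
            continue
        n_osc += 1
        autos = [cycle_event_sequence(stg, morse, c) for c in comps]
        any_hit = False
        for name, dg in data_graphs.items():
            if any(pattern_match(a, dg) for a in autos):
                per_ds[name] += 1
                any_hit = True
        if any_hit:
            matched_any += 1
    n_regions = len(regions)
    osc = n_osc / n_regions if n_regions else 0.0
    pm = matched_any / n_osc if n_osc else 0.0
    return DynamicsScores(
        n_regions=n_regions,
        n_oscillating=n_osc,
        matches_per_dataset=per_ds,
        oscillation_score=osc,
        pattern_match_score=pm,
        per_dataset_scores={k: (v / n_osc if n_osc else 0.0)
                            for k, v in per_ds.items()},
        replicate_flags={k: v > 0 for k, v in per_ds.items()},
    )
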