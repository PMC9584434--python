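"""State transition graphs and Morse graphs of a switching network.

A qualitative state assigns each node a level in ``0..out_degree``.  At a
state, a node's production value (given by the region's logic assignment
evaluated at the input levels) determines a *target level*; the node may
step one level toward its target, or stay if it is already there.  The
state transition graph (STG) has one edge per admissible single-node step.
Its strongly connected components, condensed to a DAG, form the Morse
graph; leaf components are the stable long-term behaviors, and a component
is a *full cycle* when every network node both increases and decreases
somewhere inside it (so along recurrent paths each gene attains a local
maximum and a local minimum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .netspec import RegulatoryNetwork
from .regions import ParameterRegion, RegionCapacityError, enumerate_parameter_regions


@dataclass
class StateTransitionGraph:
    """Vectorized STG of one network at one parameter region.

    ``shape[i]`` is the level count of node i; states are enumerated in
    row-major order.  ``targets[i, s]`` is node i's target level in state
    ``s``; the direction label of node i at s is ``sign(targets - level)``.
    """

    network: RegulatoryNetwork
    shape: tuple[int, ...]
    targets: np.ndarray       # (n_nodes, n_states)
    levels: np.ndarray        # (n_nodes, n_states)
    edges_from: np.ndarray    # concatenated tail state indices
    edges_to: np.ndarray      # concatenated head state indices

    @property
    def n_states(self) -> int:
        return int(np.prod(self.shape))

    def directions(self) -> np.ndarray:
        """(n_nodes, n_states) array in {-1, 0, +1}."""
        return np.sign(self.targets - self.levels).astype(np.int8)

    def adjacency(self) -> sparse.csr_matrix:
        n = self.n_states
        data = np.ones(len(self.edges_from), dtype=np.int8)
        return sparse.csr_matrix((data, (self.edges_from, self.edges_to)),
                                 shape=(n, n))


def build_stg(network: RegulatoryNetwork, region: ParameterRegion) -> StateTransitionGraph:
    """Construct the STG of ``network`` at ``region``."""
    nodes = network.nodes
    n = len(nodes)
    shape = tuple(network.levels(v) for v in nodes)
    n_states = int(np.prod(shape))

    # level of each node in each state (row-major enumeration)
    grids = np.indices(shape).reshape(n, n_states)

    # per-node input bit index and target level
    targets = np.empty((n, n_states), dtype=np.int16)
    for vi, v in enumerate(nodes):
        in_edges = network.in_edges(v)  # flattened group order = bit order
        bitvec = np.zeros(n_states, dtype=np.int64)
        for bit, (src, is_act) in enumerate(in_edges):
            si = nodes.index(src)
            # rank of the threshold that edge src->v occupies in src's order
            out_idx = network.out_targets(src).index(v)
            rank = region.assignments[si].order[out_idx]
            on = grids[si] > rank
            promoting = on if is_act else ~on
            bitvec |= promoting.astype(np.int64) << bit
        logic = np.asarray(region.assignments[vi].logic, dtype=np.int16)
        targets[vi] = logic[bitvec]

    strides = np.array([int(np.prod(shape[i + 1:])) for i in range(n)])
    froms, tos = [], []
    for vi in range(n):
        inc = np.nonzero(targets[vi] > grids[vi])[0]
        dec = np.nonzero(targets[vi] < grids[vi])[0]
        froms.append(inc)
        tos.append(inc + strides[vi])
        froms.append(dec)
        tos.append(dec - strides[vi])
    edges_from = np.concatenate(froms) if froms else np.zeros(0, dtype=int)
    edges_to = np.concatenate(tos) if tos else np.zeros(0, dtype=int)
    return StateTransitionGraph(network, shape, targets, grids, edges_from, edges_to)


@dataclass
class MorseGraph:
    """SCC condensation of an STG with stability and cycle annotations."""

    labels: np.ndarray                  # component label per STG state
    n_components: int
    dag_edges: set[tuple[int, int]]     # edges between distinct components
    stable: list[int]                   # leaf components (no out-edges)
    annotations: dict[int, str]         # 'fixed_point' | 'cycle' | 'full_cycle' | 'transient'

    def stable_full_cycles(self) -> list[int]:
        return [c for c in self.stable if self.annotations[c] == "full_cycle"]

    def has_stable_full_cycle(self) -> bool:
        return bool(self.stable_full_cycles())


def morse_graph(stg: StateTransitionGraph) -> MorseGraph:
    """Compute the Morse graph of an STG."""
    n_comp, labels = connected_components(stg.adjacency(), directed=True,
                                          connection="strong")
    return _morse_from_parts(labels, n_comp, stg.edges_from, stg.edges_to,
                             stg.directions())


def morse_graph_from_edges(n_states: int, edges: list[tuple[int, int]]) -> MorseGraph:
    """Morse graph of an arbitrary digraph (no direction annotations).

    Components are annotated 'cycle' when recurrent (a self-loop or more
    than one state) and 'fixed_point'/'transient' otherwise; the full-cycle
    refinement needs direction labels and is left out.
    """
    ef = np.array([e[0] for e in edges], dtype=int)
    et = np.array([e[1] for e in edges], dtype=int)
    adj = sparse.csr_matrix((np.ones(len(edges), dtype=np.int8), (ef, et)),
                            shape=(n_states, n_states))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    return _morse_from_parts(labels, n_comp, ef, et, None)


def _morse_from_parts(labels, n_comp, edges_from, edges_to, directions) -> MorseGraph:
    lf, lt = labels[edges_from], labels[edges_to]
    cross = lf != lt
    dag_edges = set(zip(lf[cross].tolist(), lt[cross].tolist()))
    has_out = np.zeros(n_comp, dtype=bool)
    for a, _ in dag_edges:
        has_out[a] = True
    stable = [c for c in range(n_comp) if not has_out[c]]

    sizes = np.bincount(labels, minlength=n_comp)
    has_self = np.zeros(n_comp, dtype=bool)
    same = ~cross
    has_self[np.unique(lf[same])] = True

    annotations: dict[int, str] = {}
    for c in range(n_comp):
        recurrent = sizes[c] > 1 or has_self[c]
        if not recurrent:
            annotations[c] = "transient" if has_out[c] else "fixed_point"
        elif sizes[c] == 1:
            annotations[c] = "fixed_point"
        else:
            annotations[c] = "cycle"
    if directions is not None:
        for c in range(n_comp):
            if annotations[c] != "cycle":
                continue
            member = labels == c
            d = directions[:, member]
            if np.all(np.any(d > 0, axis=1) & np.any(d < 0, axis=1)):
                annotations[c] = "full_cycle"
    return MorseGraph(labels, n_comp, dag_edges, stable, annotations)


def oscillation_score(network: RegulatoryNetwork,
                      essential_only: bool = True,
                      cap: int | None = None,
                      regions: list[ParameterRegion] | None = None,
                      max_in_degree: int = 4) -> float:
    """Fraction of parameter regions with a stable full-cycle component.

    Raises :class:`RegionCapacityError` when the region count exceeds
    ``cap`` (such networks should have been filtered by the sampler).
    """
    if regions is None:
        regions = enumerate_parameter_regions(network, essential_only, cap,
                                              max_in_degree)
    if not regions:
        return 0.0
    hits = sum(morse_graph(build_stg(network, r)).has_stable_full_cycle()
               for r in regions)
    return hits / len(regions)
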