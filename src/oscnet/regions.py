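"""Enumeration of qualitative parameter regions of a switching network.

In the switching-system semantics, each node v has one production
parameter pair ``0 < l_e < u_e`` per in-edge e and one threshold per
out-edge.  At a given qualitative state, every in-edge contributes its low
or high value (repression swaps the roles), the node's input algebra
combines them (sum within a group, product across groups), and the
resulting production value lands in one of the intervals cut out by the
node's ordered thresholds.  A *parameter region* fixes, for every node,

* a **logic assignment**: the interval index of the production value for
  each of the 2^n input combinations, and
* an **order assignment**: the total order of the node's out-thresholds,

such that the combination is realizable by actual positive parameters.
Because production strictly increases when any input flips to its
promoting state, a realizable logic is monotone over the input lattice;
monotonicity is necessary but not sufficient, so every candidate is
certified — exactly (linear programming in log-parameter space) when all
groups are singletons, and by randomized witness search with a soft-margin
refinement otherwise.

A region is *essential* when every threshold separates attained production
values (the all-low combination maps to the bottom interval and the
all-high combination to the top) and every in-edge is consequential (some
flip of that edge moves the value across a threshold).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import linprog, minimize

from .netspec import RegulatoryNetwork

#: logic[mask] = interval index for the input combination ``mask`` (bit i set
#: means in-edge i is at its promoting value)
Logic = tuple[int, ...]
#: order[k] = rank (0 = lowest threshold) of the threshold of out-edge k
Order = tuple[int, ...]


@dataclass(frozen=True)
class NodeAssignment:
    logic: Logic
    order: Order


@dataclass(frozen=True)
class ParameterRegion:
    """One qualitative parameterization of a whole network."""

    assignments: tuple[NodeAssignment, ...]  # aligned with network.nodes
    essential: bool = True


class RegionCapacityError(RuntimeError):
    """A node or network exceeds the configured combinatorial limits."""


# ---------------------------------------------------------------------------
# candidate logic enumeration


def monotone_logics(n_inputs: int, n_out: int,
                    essential_only: bool = False,
                    limit: int | None = None) -> list[Logic]:
    """All monotone maps from the n-input lattice to interval indices 0..n_out.

    With ``essential_only``, restrict to maps with ``f(0)=0`` and
    ``f(full)=n_out`` in which every input bit changes the output somewhere.
    ``limit`` aborts enumeration (raising :class:`RegionCapacityError`) once
    more than ``limit`` candidates have been produced.
    """
    n_masks = 1 << n_inputs
    top = n_masks - 1
    out: list[Logic] = []
    f = [0] * n_masks

    def rec(mask: int):
        if mask == n_masks:
            if essential_only and not _edges_essential(f, n_inputs):
                return
            out.append(tuple(f))
            if limit is not None and len(out) > limit:
                raise RegionCapacityError(
                    f"candidate logics for node signature exceed cap ({limit})")
            return
        lo = 0
        for b in range(n_inputs):
            if mask & (1 << b):
                lo = max(lo, f[mask & ~(1 << b)])
        hi = n_out
        if essential_only:
            if mask == 0:
                hi = 0
            if mask == top:
                lo = max(lo, n_out)
        for v in range(lo, hi + 1):
            f[mask] = v
            rec(mask + 1)

    rec(0)
    return out


def _edges_essential(f, n_inputs: int) -> bool:
    for b in range(n_inputs):
        bit = 1 << b
        if not any(f[m] != f[m | bit] for m in range(len(f)) if not m & bit):
            return False
    return True


def _thresholds_essential(f: Logic, n_out: int) -> bool:
    return f[0] == 0 and f[-1] == n_out


# ---------------------------------------------------------------------------
# realizability certification


def _group_bits(group_sizes: tuple[int, ...]) -> list[list[int]]:
    groups, i = [], 0
    for sz in group_sizes:
        groups.append(list(range(i, i + sz)))
        i += sz
    return groups


def _certify_lp(group_sizes: tuple[int, ...], n_out: int, logic: Logic) -> bool:
    """Exact feasibility for all-singleton-group nodes.

    In log space the production value of a combination is a sum of one
    variable per edge, so the region inequalities are linear.  The system
    is homogeneous, hence strictly feasible iff feasible with unit margin.
    """
    n = sum(group_sizes)
    # variables: [lo_0, hi_0, ..., lo_{n-1}, hi_{n-1}, t_0..t_{m-1}]
    nv = 2 * n + n_out
    rows, rhs = [], []

    def constrain(le_minus_ge: dict[int, float]):  # sum coef*x <= -1
        row = np.zeros(nv)
        for k, c in le_minus_ge.items():
            row[k] = c
        rows.append(row)
        rhs.append(-1.0)

    for e in range(n):
        constrain({2 * e: 1.0, 2 * e + 1: -1.0})          # lo < hi
    for j in range(n_out - 1):
        constrain({2 * n + j: 1.0, 2 * n + j + 1: -1.0})  # t_j < t_{j+1}
    for mask, interval in enumerate(logic):
        val = {2 * e + ((mask >> e) & 1): 1.0 for e in range(n)}
        if interval > 0:
            j = 2 * n + interval - 1                      # t_{interval-1} < value
            row = {k: -v for k, v in val.items()}
            row[j] = row.get(j, 0.0) + 1.0
            constrain(row)
        if interval < n_out:
            j = 2 * n + interval                          # value < t_interval
            row = dict(val)
            row[j] = row.get(j, 0.0) - 1.0
            constrain(row)
    res = linprog(np.zeros(nv), A_ub=np.array(rows), b_ub=np.array(rhs),
                  bounds=[(-1e4, 1e4)] * nv, method="highs")
    return res.status == 0


def _certify_numeric(group_sizes: tuple[int, ...], n_out: int, logic: Logic,
                     n_restarts: int = 24, seed: int = 0) -> bool:
    """Soft-margin witness search for nodes with sum groups.

    Minimizes a smooth penalty on violated log-inequalities from random
    log-uniform starts; success within tolerance certifies realizability.
    Failure after all restarts is reported as unrealizable (heuristic,
    calibrated against brute-force sampling oracles on small signatures).
    """
    n = sum(group_sizes)
    groups = _group_bits(group_sizes)
    rng = np.random.default_rng(seed)
    margin = 0.05

    masks = np.arange(1 << n)
    bits = ((masks[:, None] >> np.arange(n)[None, :]) & 1).astype(bool)
    logic_arr = np.array(logic)

    def penalty(x):
        x = np.clip(x, -40.0, 40.0)
        lo = np.exp(x[:n])
        hi = lo + np.exp(x[n:2 * n])
        thr = np.cumsum(np.exp(x[2 * n:]))
        vals = np.where(bits, hi[None, :], lo[None, :])
        prod = np.ones(len(masks))
        for g in groups:
            prod = prod * vals[:, g].sum(axis=1)
        logv = np.log(prod)
        logt = np.log(thr) if n_out else np.zeros(0)
        total = 0.0
        iv = logic_arr
        # value above threshold iv-1, below threshold iv
        has_lower = iv > 0
        has_upper = iv < n_out
        lowers = logt[iv[has_lower] - 1] - logv[has_lower] + margin
        uppers = logv[has_upper] - logt[iv[has_upper]] + margin
        for arr in (lowers, uppers):
            v = np.logaddexp(0.0, arr / 0.01) * 0.01  # softplus
            total += float(np.sum(v ** 2))
        return total

    for _ in range(n_restarts):
        x0 = rng.uniform(-2.0, 2.0, size=2 * n + n_out)
        res = minimize(penalty, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "fatol": 1e-12, "xatol": 1e-8})
        if res.fun < 1e-10:
            return True
    return False


@lru_cache(maxsize=None)
def _realizable(group_sizes: tuple[int, ...], n_out: int, logic: Logic) -> bool:
    if all(sz == 1 for sz in group_sizes):
        return _certify_lp(group_sizes, n_out, logic)
    return _certify_numeric(group_sizes, n_out, logic)


def sample_node_patterns(group_sizes: tuple[int, ...], n_out: int,
                         n_samples: int = 20000, seed: int = 1) -> set[Logic]:
    """Brute-force randomized oracle: observed logic patterns of a node.

    Draws log-uniform positive parameters and records which interval each
    input combination's production value falls into.  Independent of the
    certification path; used to cross-check enumeration on small nodes.
    """
    n = sum(group_sizes)
    groups = _group_bits(group_sizes)
    rng = np.random.default_rng(seed)
    masks = np.arange(1 << n)
    bits = ((masks[:, None] >> np.arange(n)[None, :]) & 1).astype(bool)
    seen: set[Logic] = set()
    for _ in range(n_samples):
        lo = np.exp(rng.uniform(-4, 4, size=n))
        hi = lo + np.exp(rng.uniform(-4, 4, size=n))
        thr = np.sort(np.exp(rng.uniform(-6, 6, size=n_out)))
        vals = np.where(bits, hi[None, :], lo[None, :])
        prod = np.ones(len(masks))
        for g in groups:
            prod = prod * vals[:, g].sum(axis=1)
        seen.add(tuple(int(np.searchsorted(thr, v)) for v in prod))
    return seen


# ---------------------------------------------------------------------------
# per-node and per-network enumeration


@lru_cache(maxsize=None)
def node_logics(group_sizes: tuple[int, ...], n_out: int,
                essential_only: bool = True,
                limit: int | None = None) -> tuple[Logic, ...]:
    """Realizable (and optionally essential) logic assignments of one node."""
    n = sum(group_sizes)
    cands = monotone_logics(n, n_out, essential_only=essential_only, limit=limit)
    good = []
    for f in cands:
        if essential_only and not _thresholds_essential(f, n_out):
            continue
        if _realizable(group_sizes, n_out, f):
            good.append(f)
    return tuple(good)


def node_assignment_count(group_sizes: tuple[int, ...], n_out: int,
                          essential_only: bool = True,
                          limit: int | None = None) -> int:
    import math
    return len(node_logics(group_sizes, n_out, essential_only, limit)) * math.factorial(n_out)


def _node_signature(network: RegulatoryNetwork, node: str) -> tuple[tuple[int, ...], int]:
    groups = network.in_groups(node)
    return tuple(len(g) for g in groups), network.out_degree(node)


def count_parameter_regions(network: RegulatoryNetwork,
                            essential_only: bool = True,
                            cap: int | None = None,
                            max_in_degree: int = 4) -> int:
    """Product over nodes of realizable assignment counts.

    ``cap`` aborts with :class:`RegionCapacityError` once the running
    product exceeds it; ``max_in_degree`` bounds per-node input complexity.
    """
    total = 1
    for v in network.nodes:
        sizes, m = _node_signature(network, v)
        if sum(sizes) > max_in_degree:
            raise RegionCapacityError(
                f"node {v} has in-degree {sum(sizes)} > limit {max_in_degree}")
        per_node_limit = None if cap is None else max(cap // max(total, 1), 1) * 2
        total *= node_assignment_count(sizes, m, essential_only, per_node_limit)
        if cap is not None and total > cap:
            raise RegionCapacityError(
                f"region count exceeds cap {cap} at node {v}")
        if total == 0:
            return 0
    return total


def enumerate_parameter_regions(network: RegulatoryNetwork,
                                essential_only: bool = True,
                                cap: int | None = None,
                                max_in_degree: int = 4) -> list[ParameterRegion]:
    """Materialize all parameter regions (product across nodes)."""
    count_parameter_regions(network, essential_only, cap, max_in_degree)
    per_node: list[list[NodeAssignment]] = []
    for v in network.nodes:
        sizes, m = _node_signature(network, v)
        logics = node_logics(sizes, m, essential_only)
        assigns = [NodeAssignment(f, perm)
                   for f in logics
                   for perm in itertools.permutations(range(m))]
        per_node.append(assigns)
    return [ParameterRegion(tuple(combo), essential_only)
            for combo in itertools.product(*per_node)]
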