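"""Extremum events and data graphs.

A time series is summarized by the partial order of its local maxima and
minima.  At noise level ``epsilon`` (a fraction of the trace's global
range), wiggles whose amplitude does not exceed ``epsilon * range`` are
merged away, and each surviving extremum carries an uncertainty interval —
the maximal time window over which the trace stays within ``epsilon *
range`` of the extremal value.  Two events are ordered in the *data graph*
exactly when their uncertainty intervals are disjoint in time (plus the
always-known ordering of consecutive events of one gene); the result is a
DAG whose edges are the noise-robust precedences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeseries import TimeSeriesSet

MAX = "max"
MIN = "min"


@dataclass(frozen=True)
class ExtremumEvent:
    gene: str
    kind: str                 # MAX or MIN
    nominal_time: float
    t_lo: float
    t_hi: float

    def __post_init__(self) -> None:
        if not self.t_lo <= self.nominal_time <= self.t_hi:
            raise ValueError("nominal time outside uncertainty interval")

    @property
    def label(self) -> tuple[str, str]:
        return (self.gene, self.kind)


@dataclass
class DataGraph:
    """DAG of extremum events ordered by disjoint uncertainty intervals."""

    events: list[ExtremumEvent]
    edges: set[tuple[int, int]] = field(default_factory=set)  # (before, after)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def predecessors_mask(self) -> list[int]:
        """Bitmask of must-precede events for each event (direct edges)."""
        pred = [0] * self.n_events
        for a, b in self.edges:
            pred[b] |= 1 << a
        return pred

    def genes(self) -> set[str]:
        return {e.gene for e in self.events}

    def project(self, genes) -> "DataGraph":
        """Restrict to events of ``genes`` (precedences recomputed)."""
        keep = [i for i, e in enumerate(self.events) if e.gene in genes]
        remap = {old: new for new, old in enumerate(keep)}
        events = [self.events[i] for i in keep]
        edges = {(remap[a], remap[b]) for a, b in self.edges
                 if a in remap and b in remap}
        return DataGraph(events, edges)


def extract_events(trace: np.ndarray, times: np.ndarray,
                   epsilon: float = 0.0, gene: str = "") -> list[ExtremumEvent]:
    """Alternating max/min events of one trace at noise level ``epsilon``.

    ``epsilon`` must lie in [0, 1); the merge threshold is ``epsilon``
    times the trace's global range.  Requires at least 3 samples.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if trace.size < 3:
        raise ValueError("need at least 3 samples to find extrema")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must be in [0, 1)")
    rng = float(trace.max() - trace.min())
    if rng == 0.0:
        return []
    delta = epsilon * rng

    idx = _alternating_extrema(trace)
    idx = _merge_small_wiggles(trace, idx, delta)
    events = []
    for i in idx:
        kind = MAX if _is_local_max(trace, i) else MIN
        lo, hi = _uncertainty_interval(trace, times, i, delta)
        events.append(ExtremumEvent(gene, kind, float(times[i]), lo, hi))
    return events


def _is_local_max(trace, i) -> bool:
    left = trace[:i][::-1]
    right = trace[i + 1:]
    lv = next((v for v in left if v != trace[i]), None)
    rv = next((v for v in right if v != trace[i]), None)
    higher = trace[i]
    return (lv is None or lv < higher) and (rv is None or rv < higher)


def _alternating_extrema(trace: np.ndarray) -> list[int]:
    """Indices of interior strict direction changes (plateau-aware)."""
    out = []
    n = trace.size
    last_dir = 0
    for i in range(1, n):
        d = np.sign(trace[i] - trace[i - 1])
        if d == 0:
            continue
        if last_dir != 0 and d != last_dir:
            # turning point is the previous distinct sample
            j = i - 1
            while j > 0 and trace[j] == trace[j - 1]:
                j -= 1
            out.append(j)
        last_dir = d
    return out


def _merge_small_wiggles(trace: np.ndarray, idx: list[int], delta: float) -> list[int]:
    """Drop adjacent extremum pairs whose amplitude difference is <= delta."""
    idx = list(idx)
    while len(idx) >= 2:
        gaps = [abs(trace[idx[k + 1]] - trace[idx[k]]) for k in range(len(idx) - 1)]
        k = int(np.argmin(gaps))
        if gaps[k] > delta:
            break
        del idx[k:k + 2]  # removing the adjacent pair preserves alternation
    return idx


def _uncertainty_interval(trace, times, i, delta) -> tuple[float, float]:
    lo = i
    while lo > 0 and abs(trace[lo - 1] - trace[i]) <= delta:
        lo -= 1
    hi = i
    while hi < trace.size - 1 and abs(trace[hi + 1] - trace[i]) <= delta:
        hi += 1
    return float(times[lo]), float(times[hi])


def build_data_graph(events_by_gene: dict[str, list[ExtremumEvent]]) -> DataGraph:
    """Assemble per-gene event lists into a data graph.

    Precedence between any two events requires wholly disjoint uncertainty
    intervals; consecutive events of one gene are ordered regardless.
    """
    events: list[ExtremumEvent] = []
    intra: set[tuple[int, int]] = set()
    for gene, evs in events_by_gene.items():
        start = len(events)
        for k, e in enumerate(evs):
            if k > 0 and evs[k - 1].kind == e.kind:
                raise ValueError(f"events of gene {gene} must alternate max/min")
            events.append(e)
            if k > 0:
                intra.add((start + k - 1, start + k))
    edges = set(intra)
    for a in range(len(events)):
        for b in range(len(events)):
            if a != b and events[a].t_hi < events[b].t_lo:
                edges.add((a, b))
    dg = DataGraph(events, edges)
    _assert_acyclic(dg)
    return dg


def _assert_acyclic(dg: DataGraph) -> None:
    indeg = [0] * dg.n_events
    for _, b in dg.edges:
        indeg[b] += 1
    queue = [i for i, d in enumerate(indeg) if d == 0]
    seen = 0
    succ: dict[int, list[int]] = {}
    for a, b in dg.edges:
        succ.setdefault(a, []).append(b)
    while queue:
        x = queue.pop()
        seen += 1
        for y in succ.get(x, ()):
            indeg[y] -= 1
            if indeg[y] == 0:
                queue.append(y)
    if seen != dg.n_events:
        raise RuntimeError("internal error: cyclic precedence in data graph")


def write_data_graph(dg: DataGraph, path) -> None:
    """Serialize a data graph as an event-list TSV plus precedence pairs."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("event_id\tgene\tkind\tnominal_time\tt_lo\tt_hi\n")
        for i, e in enumerate(dg.events):
            fh.write(f"{i}\t{e.gene}\t{e.kind}\t{e.nominal_time:.10g}"
                     f"\t{e.t_lo:.10g}\t{e.t_hi:.10g}\n")
        fh.write("# precedence\n")
        for a, b in sorted(dg.edges):
            fh.write(f"{a}\t{b}\n")


def read_data_graph(path) -> DataGraph:
    events: list[ExtremumEvent] = []
    edges: set[tuple[int, int]] = set()
    in_edges = False
    with open(path, encoding="utf-8") as fh:
        next(fh)  # header
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith("# precedence"):
                in_edges = True
                continue
            cells = ln.split("\t")
            if in_edges:
                edges.add((int(cells[0]), int(cells[1])))
            else:
                events.append(ExtremumEvent(cells[1], cells[2],
                                            float(cells[3]), float(cells[4]),
                                            float(cells[5])))
    return DataGraph(events, edges)


def estimate_period(ts: TimeSeriesSet, transient_fraction: float = 0.5) -> float:
    """Median spacing of successive maxima across genes, post-transient."""
    t0 = ts.times[0] + transient_fraction * (ts.times[-1] - ts.times[0])
    for window in (ts.window(t0, ts.times[-1]), ts):  # fall back to full series
        spacings = []
        for g in window.gene_names:
            evs = [e for e in extract_events(window.trace(g), window.times, 0.0, g)
                   if e.kind == MAX]
            tt = [e.nominal_time for e in evs]
            spacings.extend(np.diff(tt))
        if spacings:
            return float(np.median(spacings))
    raise ValueError("no repeated maxima; cannot estimate a period")


def periodic_data_graph(ts: TimeSeriesSet, epsilon: float = 0.0,
                        transient_fraction: float = 0.5) -> DataGraph:
    """Data graph of one period of an oscillatory dataset.

    The transient is discarded, the common period is estimated from maxima
    spacings, and events are collected over a single period window on the
    attractor.  Used by the network-scoring stage, whose cyclic matching
    convention expects one period of events.
    """
    period = estimate_period(ts, transient_fraction)
    t0 = ts.times[0] + transient_fraction * (ts.times[-1] - ts.times[0])
    by_gene: dict[str, list[ExtremumEvent]] = {}
    for g in ts.gene_names:
        evs = extract_events(ts.trace(g), ts.times, epsilon, g)
        win = [e for e in evs if t0 <= e.nominal_time < t0 + period]
        if win:
            by_gene[g] = win
    return build_data_graph(by_gene)
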