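"""Node finding: rank genes by joint periodicity and amplitude variability.

Two per-gene p-values are combined.  The *regulator score* of a trace is
the (population) standard deviation of the base-10 logarithm of the
mean-normalized profile; its empirical p-value ``p_reg`` is the fraction
of random curves — built by copying, at each time point, the value of a
uniformly drawn dataset curve — whose regulator score strictly exceeds the
gene's.  The *periodicity p-value* ``p_per`` comes from a nonparametric
rank test: the trace's pairwise up/down pattern is compared with cosine
templates over a user period list and phase grid via Kendall's tau, and
the best concordance is converted to an exact tail probability under the
permutation null, Bonferroni-multiplied by the number of templates.

The combined score (lower = better core-gene candidate) is

    score = p_reg * p_per * [1 + (p_reg/0.001)^2] * [1 + (p_per/0.001)^2]

which accentuates genes that are simultaneously highly periodic and
highly variable in amplitude.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core import RankingTable
from .timeseries import TimeSeriesSet

KNEE = 0.001  # soft knee of the combination formula


def regulator_score(trace: np.ndarray, pseudo_count: float = 0.0) -> float:
    """Population std of log10 of the mean-normalized trace.

    Traces must be strictly positive; a documented pseudo-count option
    (disabled by default) shifts the trace before taking logs.
    """
    x = np.asarray(trace, dtype=float) + pseudo_count
    if np.any(x <= 0):
        raise ValueError(
            "regulator score requires positive values; "
            "consider the pseudo_count option for zero-containing traces")
    logs = np.log10(x / x.mean())
    return float(np.std(logs))  # population convention (divide by T)


def empirical_p_reg(gene: str, dataset: TimeSeriesSet, n_r: int,
                    rng: np.random.Generator) -> float:
    """Fraction of ``n_r`` random curves whose regulator score strictly
    exceeds the gene's."""
    if n_r < 1:
        raise ValueError("n_r must be >= 1")
    target = regulator_score(dataset.trace(gene))
    picks = rng.integers(0, dataset.n_genes, size=(n_r, dataset.n_times))
    curves = dataset.values[picks, np.arange(dataset.n_times)[None, :]]
    exceed = 0
    for row in curves:
        if regulator_score(row) > target:
            exceed += 1
    return exceed / n_r


# ---------------------------------------------------------------------------
# rank-correlation periodicity test


def _pair_signs(x: np.ndarray) -> np.ndarray:
    d = np.subtract.outer(x, x)
    return np.sign(d[np.triu_indices(len(x), k=1)])


def kendall_s(x: np.ndarray, y: np.ndarray) -> int:
    """Concordances minus discordances over all time pairs."""
    return int(np.sum(_pair_signs(np.asarray(x)) * _pair_signs(np.asarray(y))))


def exact_null_s(trace_values: tuple[float, ...], template_values: tuple[float, ...],
                 n_mc: int = 20000, mc_seed: int = 0) -> dict[int, float]:
    """Null distribution of the concordance statistic S.

    Under the null, the trace values are uniformly permuted against the
    fixed template.  For up to 8 samples the distribution is computed by
    exhaustive enumeration (ties in either vector handled exactly).  For
    longer untied inputs the classical inversion-count recursion gives the
    exact distribution; otherwise a seeded permutation sample is used and
    a warning issued.
    """
    n = len(trace_values)
    x = np.asarray(trace_values, dtype=float)
    y = np.asarray(template_values, dtype=float)
    if n <= 8:
        return _null_by_enumeration(x, y)
    if len(set(trace_values)) == n and len(set(template_values)) == n:
        return _null_untied(n)
    warnings.warn("tied values with n > 8: falling back to a seeded "
                  "permutation approximation of the concordance null")
    return _null_by_sampling(x, y, n_mc, mc_seed)


def _null_by_enumeration(x: np.ndarray, y: np.ndarray) -> dict[int, float]:
    n = len(x)
    sy = _pair_signs(y)
    iu, ju = np.triu_indices(n, k=1)
    counts: dict[int, int] = {}
    total = 0
    for perm in itertools.permutations(range(n)):
        xp = x[list(perm)]
        s = int(np.sum(np.sign(xp[ju] - xp[iu]) * sy))
        counts[s] = counts.get(s, 0) + 1
        total += 1
    return {s: c / total for s, c in counts.items()}


@lru_cache(maxsize=64)
def _null_untied(n: int) -> dict[int, float]:
    # number of permutations with k discordant pairs: coefficients of
    # prod_{i=1}^{n} (1 + x + ... + x^{i-1})
    coeffs = np.array([1.0])
    for i in range(1, n + 1):
        kernel = np.ones(i)
        coeffs = np.convolve(coeffs, kernel)
    total = math.factorial(n)
    npairs = n * (n - 1) // 2
    return {npairs - 2 * k: c / total for k, c in enumerate(coeffs)}


def _null_by_sampling(x, y, n_mc, seed) -> dict[int, float]:
    rng = np.random.default_rng(seed)
    sy = _pair_signs(y)
    n = len(x)
    iu, ju = np.triu_indices(n, k=1)
    counts: dict[int, int] = {}
    for _ in range(n_mc):
        xp = rng.permutation(x)
        s = int(np.sum(np.sign(xp[ju] - xp[iu]) * sy))
        counts[s] = counts.get(s, 0) + 1
    return {s: c / n_mc for s, c in counts.items()}


def cosine_templates(times: np.ndarray, periods, n_phases: int | None = None
                     ) -> list[np.ndarray]:
    """Cosine reference curves for each (period, phase) combination.

    Phases are evenly spaced offsets over one period; the default count
    equals the number of sample times, so anti-phase templates are always
    present and two-sidedness is handled by the grid itself.
    """
    times = np.asarray(times, dtype=float)
    if n_phases is None:
        n_phases = times.size
    out = []
    for p in periods:
        for k in range(n_phases):
            phi = p * k / n_phases
            out.append(np.cos(2 * np.pi * (times - phi) / p))
    return out


def jtk_p_per(trace: np.ndarray, times: np.ndarray, periods,
              n_phases: int | None = None) -> float:
    """Bonferroni-adjusted exact tail p-value of the best template match."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        raise ValueError("need at least 3 time points")
    templates = cosine_templates(times, periods, n_phases)
    if not templates:
        raise ValueError("need at least one template")
    if np.all(trace == trace[0]):
        warnings.warn("constant trace: concordance undefined, p_per = 1")
        return 1.0
    best_p = 1.0
    for tmpl in templates:
        s_obs = kendall_s(trace, tmpl)
        null = exact_null_s(tuple(trace), tuple(tmpl))
        tail = sum(p for s, p in null.items() if s >= s_obs)
        best_p = min(best_p, tail)
    return min(1.0, best_p * len(templates))


# ---------------------------------------------------------------------------
# combination and ranking


def dlxjtk_score(p_reg: float, p_per: float) -> float:
    """Combine the amplitude and periodicity p-values (lower = better)."""
    if not (0.0 <= p_reg <= 1.0 and 0.0 < p_per <= 1.0):
        raise ValueError("p_reg in [0,1] and p_per in (0,1] required")
    return (p_reg * p_per
            * (1.0 + (p_reg / KNEE) ** 2)
            * (1.0 + (p_per / KNEE) ** 2))


@dataclass(frozen=True)
class NodeScore:
    gene: str
    p_reg: float
    p_per: float
    dlxjtk: float
    n_r: int


def score_nodes(dataset: TimeSeriesSet, periods, n_r: int,
                rng: np.random.Generator,
                n_phases: int | None = None) -> list[NodeScore]:
    out = []
    for g in dataset.gene_names:
        pr = empirical_p_reg(g, dataset, n_r, rng)
        pp = jtk_p_per(dataset.trace(g), dataset.times, periods, n_phases)
        out.append(NodeScore(g, pr, pp, dlxjtk_score(pr, pp), n_r))
    return out


def write_node_ranking(table: RankingTable, node_scores: list[NodeScore],
                       path) -> None:
    """Node ranking TSV with columns gene, p_reg, p_per, dlxjtk, rank."""
    by_gene = {s.gene: s for s in node_scores}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tp_reg\tp_per\tdlxjtk\trank\n")
        for gene, score, rank in table.items:
            s = by_gene[gene]
            fh.write(f"{gene}\t{s.p_reg:.6g}\t{s.p_per:.6g}"
                     f"\t{s.dlxjtk:.6g}\t{rank:g}\n")


def rank_nodes(node_scores: list[NodeScore], top_k: int | None = None
               ) -> RankingTable:
    """Ascending ranking by combined score; optionally truncated to top_k."""
    if not node_scores:
        raise ValueError("no node scores to rank")
    table = RankingTable.from_scores({s.gene: s.dlxjtk for s in node_scores},
                                     direction="lower_is_better")
    if top_k is not None:
        table = RankingTable(table.items[:top_k], table.direction,
                             table.tiebreak_note)
    return table
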