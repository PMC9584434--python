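"""Edge finding: Bayesian ranking of single-edge regulation models.

For every allowed (target, source, sign) hypothesis, the five-parameter
Hill model is fitted to the target trace driven by the source trace, the
Laplace log-evidence is computed, and — per target — evidences are turned
into a posterior over that target's allowed models (the *pld score*).
Replicate datasets chain: the posterior from one replicate becomes the
prior for the next.  Merging all targets' models and sorting by pld
descending yields the local edge ranking; the local node participation
score of a gene is the median rank of its incident edges within a chosen
restriction of that ranking.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np

from .core import ACTIVATION, REPRESSION, EdgeHypothesis, GeneAnnotation, RankingTable
from .hill import (DIM, FitHyperparams, HillParams, fd_hessian, fit_energy,
                   fit_edge_model, laplace_log_evidence, make_mse_objective)
from .timeseries import TimeSeriesSet

log = logging.getLogger(__name__)


@dataclass
class EdgeModelResult:
    hypothesis: EdgeHypothesis
    optimum: HillParams
    loss_at_opt: float
    log_evidence: float
    pld: float = 0.0


def enumerate_hypotheses(nodes: list[str],
                         annotations: dict[str, GeneAnnotation] | None = None
                         ) -> list[EdgeHypothesis]:
    """All allowed (target, source, sign) combinations.

    Without annotations this is N targets x N sources x 2 signs.  With
    annotations, target-only genes contribute no out-edges, single-role
    regulators only their allowed sign, and non-target genes never appear
    as targets.
    """
    if not nodes:
        raise ValueError("node list is empty")
    annotations = annotations or {}
    for g in annotations:
        if g not in nodes:
            raise ValueError(f"annotation references unknown gene {g!r}")

    def ann(g: str) -> GeneAnnotation:
        return annotations.get(g, GeneAnnotation(g))

    out = []
    for target in nodes:
        if not ann(target).may_be_target:
            continue
        for source in nodes:
            for sign in (ACTIVATION, REPRESSION):
                if ann(source).allows(sign, as_source=True):
                    out.append(EdgeHypothesis(target, source, sign))
    return out


def pld_posterior(log_evidences: list[float],
                  prior: list[float] | None = None) -> list[float]:
    """Normalize evidences into a posterior (log-domain softmax).

    ``prior`` defaults to uniform over the target's allowed models.  If
    every evidence is -inf the posterior degrades to the prior with a
    warning.
    """
    m = len(log_evidences)
    if m == 0:
        raise ValueError("no models for target")
    prior = prior if prior is not None else [1.0 / m] * m
    if abs(sum(prior) - 1.0) > 1e-9:
        raise ValueError("prior must sum to 1 over the target's models")
    logs = np.asarray(log_evidences, dtype=float)
    logp = np.log(np.maximum(prior, 1e-300))
    combined = logs + logp
    if not np.any(np.isfinite(combined)):
        log.warning("all model evidences vanished; returning prior")
        return list(prior)
    c = combined - np.max(combined[np.isfinite(combined)])
    w = np.where(np.isfinite(c), np.exp(c), 0.0)
    return list(w / w.sum())


def _fit_rng(master_seed: int, key: str, tgt: np.ndarray, reg: np.ndarray
             ) -> np.random.Generator:
    """Fit randomness derived from the master seed and the data content.

    Identical (hypothesis, data) pairs produce identical fits regardless
    of evaluation order, which makes whole runs reproducible and lets
    replicate chaining on identical replicates reduce exactly to squaring
    the likelihoods.
    """
    digest = zlib.crc32(key.encode() + tgt.tobytes() + reg.tobytes())
    return np.random.default_rng([master_seed & 0x7FFFFFFF, digest])


def evaluate_target(target: str,
                    hypotheses: list[EdgeHypothesis],
                    replicates: list[TimeSeriesSet],
                    hyper: FitHyperparams,
                    rng: np.random.Generator) -> list[EdgeModelResult]:
    """Fit, weigh and chain all models of one target across replicates."""
    models = [h for h in hypotheses if h.target == target]
    if not models:
        return []
    master_seed = int(rng.integers(2 ** 31 - 1))
    prior = [1.0 / len(models)] * len(models)
    results: list[EdgeModelResult] = []
    for rep in replicates:
        fits = []
        for h in models:
            tgt = rep.trace(h.target)
            reg = rep.trace(h.source)
            opt, loss = fit_edge_model(tgt, reg, rep.times, h.sign, hyper,
                                       _fit_rng(master_seed, h.key, tgt, reg))
            fits.append((h, opt, loss))
        sigma2 = max(min(loss for _, _, loss in fits), 1e-12)
        evidences = []
        for h, opt, loss in fits:
            mse_of = make_mse_objective(rep.trace(h.target),
                                        rep.trace(h.source), rep.times,
                                        h.sign, hyper.substeps)

            def energy(x, _mse=mse_of):
                return fit_energy(_mse(x), rep.n_times, sigma2)

            e_star = fit_energy(loss, rep.n_times, sigma2)
            H = fd_hessian(energy, opt.as_array())
            evidences.append(laplace_log_evidence(e_star, H, DIM))
        prior = pld_posterior(evidences, prior)
        results = [EdgeModelResult(h, opt, loss, ev, pld)
                   for (h, opt, loss), ev, pld in zip(fits, evidences, prior)]
    return results


def run_edge_finding(replicates: list[TimeSeriesSet],
                     hyper: FitHyperparams,
                     rng: np.random.Generator,
                     annotations: dict[str, GeneAnnotation] | None = None
                     ) -> list[EdgeModelResult]:
    """Evaluate every allowed hypothesis on the replicate datasets."""
    if not replicates:
        raise ValueError("at least one replicate dataset required")
    nodes = list(replicates[0].gene_names)
    hypotheses = enumerate_hypotheses(nodes, annotations)
    out: list[EdgeModelResult] = []
    for target in nodes:
        out.extend(evaluate_target(target, hypotheses, replicates, hyper, rng))
    return out


def local_edge_ranking(results: list[EdgeModelResult]) -> RankingTable:
    """All hypotheses merged and ranked by pld descending."""
    return RankingTable.from_scores(
        {r.hypothesis.key: r.pld for r in results},
        direction="higher_is_better")


def node_participation(ranking: RankingTable, node_set: list[str],
                       restrict_to: list[str] | None = None) -> RankingTable:
    """Median rank of each node's incident edges within a restriction.

    ``restrict_to`` is a list of edge keys (default: all ranked edges).  A
    node incident to no restricted edge gets the worst possible score —
    the restriction size — and is flagged in the tie-break note.
    """
    keys = restrict_to if restrict_to is not None else ranking.keys
    keyset = set(keys)
    for k in keyset:
        if k not in set(ranking.keys):
            raise ValueError(f"restriction edge {k} not in ranking")
    worst = float(len(keys))
    flagged = []
    scores: dict[str, float] = {}
    for node in node_set:
        ranks = []
        for k in keys:
            e = EdgeHypothesis.from_key(k)
            if node in (e.source, e.target):
                ranks.append(ranking.rank_of(k))
        if ranks:
            scores[node] = float(np.median(ranks))
        else:
            scores[node] = worst
            flagged.append(node)
    note = "ties broken by lexicographic item key"
    if flagged:
        note += f"; no incident restricted edge (worst score): {','.join(sorted(flagged))}"
    return RankingTable.from_scores(scores, "lower_is_better", note)
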