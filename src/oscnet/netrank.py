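"""Top-network selection, edge prevalence, and global rankings.

Sampled networks are filtered by user criteria on their oscillation and
pattern-match scores (optionally requiring a match in every replicate).
Each candidate edge's *prevalence* is the fraction P = N/T of the T top
networks containing it; the *global edge ranking* sorts candidates by
prevalence (ties broken by local edge rank) with every zero-prevalence
edge assigned the single worst rank — the number of candidate edges.
Comparing local and global node participation scores yields the
experiment-prioritization report: nodes whose global score improves on
their local score are promising intervention targets, nodes that are
downranked are candidates for dismissal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import EdgeHypothesis, RankingTable
from .edgefind import node_participation
from .match import DynamicsScores
from .netspec import RegulatoryNetwork

log = logging.getLogger(__name__)


@dataclass
class NetworkScore:
    """Scores of one sampled network."""

    network_id: str
    network: RegulatoryNetwork
    oscillation_score: float
    pattern_match_score: float
    replicate_flags: dict[str, bool]
    n_regions: int = 0

    def __post_init__(self) -> None:
        if self.oscillation_score == 0.0 and self.pattern_match_score != 0.0:
            raise ValueError("pattern match score must vanish without oscillation")

    @classmethod
    def from_dynamics(cls, network_id: str, network: RegulatoryNetwork,
                      scores: DynamicsScores) -> "NetworkScore":
        return cls(network_id, network, scores.oscillation_score,
                   scores.pattern_match_score, dict(scores.replicate_flags),
                   scores.n_regions)


@dataclass
class TopNetworkCriteria:
    oscillation_min: float = 1.0
    oscillation_max: float = 1.0
    pattern_match_min: float = 0.5
    require_all_replicates: bool = False

    def __post_init__(self) -> None:
        if self.oscillation_min > self.oscillation_max:
            raise ValueError("oscillation window has lo > hi")

    def admits(self, s: NetworkScore) -> bool:
        if not self.oscillation_min <= s.oscillation_score <= self.oscillation_max:
            return False
        if s.pattern_match_score < self.pattern_match_min:
            return False
        if self.require_all_replicates and not all(s.replicate_flags.values()):
            return False
        return True


def select_top_networks(scores: list[NetworkScore],
                        criteria: TopNetworkCriteria) -> list[NetworkScore]:
    """Networks meeting all criteria (may be empty, which is logged loudly)."""
    top = [s for s in scores if criteria.admits(s)]
    if not top:
        log.warning("no network met the top-network criteria "
                    "(osc in [%g, %g], pattern match >= %g)",
                    criteria.oscillation_min, criteria.oscillation_max,
                    criteria.pattern_match_min)
    return top


@dataclass(frozen=True)
class EdgePrevalence:
    edge: EdgeHypothesis
    n_present: int
    n_top: int

    @property
    def prevalence(self) -> float:
        return self.n_present / self.n_top if self.n_top else 0.0


def edge_prevalence(top_networks: list[NetworkScore],
                    candidate_edges: list[EdgeHypothesis]
                    ) -> list[EdgePrevalence]:
    """Prevalence of every candidate edge among the top networks."""
    t = len(top_networks)
    if t == 0:
        log.warning("empty top-network set: all prevalences are zero")
    out = []
    edge_sets = [set(s.network.edges) for s in top_networks]
    for e in candidate_edges:
        n = sum(e in es for es in edge_sets)
        out.append(EdgePrevalence(e, n, t))
    return out


def global_edge_ranking(prevalences: list[EdgePrevalence],
                        local_ranking: RankingTable) -> RankingTable:
    """Rank candidates by prevalence; zero-prevalence edges share the
    worst rank (= the candidate count)."""
    worst = float(len(prevalences))
    nonzero = [p for p in prevalences if p.n_present > 0]
    nonzero.sort(key=lambda p: (-p.prevalence, local_ranking.rank_of(p.edge.key)))
    items = [(p.edge.key, p.prevalence, float(r))
             for r, p in enumerate(nonzero, start=1)]
    for p in sorted((p for p in prevalences if p.n_present == 0),
                    key=lambda p: p.edge.key):
        items.append((p.edge.key, 0.0, worst))
    return RankingTable(
        items, "higher_is_better",
        "prevalence ties broken by local edge rank; zero-prevalence edges "
        f"share the worst rank {worst:g}")


@dataclass
class NodeComparison:
    node: str
    local_score: float
    global_score: float

    @property
    def delta(self) -> float:
        """Positive when the node is upranked by the global analysis."""
        return self.local_score - self.global_score


def compare_rankings(local_ranking: RankingTable,
                     global_ranking: RankingTable,
                     node_set: list[str],
                     edge_restriction: list[str]) -> list[NodeComparison]:
    """Per-node local vs global participation on a shared edge restriction."""
    if not edge_restriction:
        raise ValueError("empty edge restriction")
    local_part = node_participation(local_ranking, node_set, edge_restriction)
    global_part = node_participation(global_ranking, node_set, edge_restriction)
    return [NodeComparison(v, local_part.score_of(v), global_part.score_of(v))
            for v in node_set]


def write_comparison(rows: list[NodeComparison], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tlocal_score\tglobal_score\tdelta\n")
        for r in rows:
            fh.write(f"{r.node}\t{r.local_score:g}\t{r.global_score:g}\t{r.delta:g}\n")


def summarize_comparisons(runs: list[list[NodeComparison]]
                          ) -> dict[str, tuple[float, float, float, float]]:
    """Mean +/- sd of local and global scores across repeated runs.

    Returns node -> (local_mean, local_sd, global_mean, global_sd).
    """
    nodes = [c.node for c in runs[0]]
    out = {}
    for v in nodes:
        loc = np.array([next(c.local_score for c in run if c.node == v)
                        for run in runs])
        glo = np.array([next(c.global_score for c in run if c.node == v)
                        for run in runs])
        out[v] = (float(loc.mean()), float(loc.std()),
                  float(glo.mean()), float(glo.std()))
    return out
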