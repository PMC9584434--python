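"""Stochastic search of network space around a seed network.

The seed network is induced by all edges whose posterior (pld) exceeds a
threshold; the candidate pool adds the next K ranked edges (self-repressing
edges removed).  Starting from the seed, each sampling attempt applies a
random number of moves — add node, add edge, drop node, drop edge, drawn
by the configured probabilities — and the result is accepted when it is
strongly connected, within the parameter-region cap, and free of
self-repression.  Accepted networks are deduplicated by canonical
serialization and sampling continues until the requested number of unique
networks (or the attempt budget) is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import NetworkFindingConfig
from .core import EdgeHypothesis, RankingTable
from .netspec import RegulatoryNetwork
from .regions import RegionCapacityError, count_parameter_regions

log = logging.getLogger(__name__)


def seed_network(local_ranking: RankingTable, pld_threshold: float
                 ) -> RegulatoryNetwork:
    """Network induced by all edges with pld strictly above the threshold."""
    if not 0.0 <= pld_threshold <= 1.0:
        raise ValueError("pld threshold must be in [0, 1]")
    edges = [EdgeHypothesis.from_key(k) for k, score, _ in local_ranking.items
             if score > pld_threshold]
    return RegulatoryNetwork.from_edges(edges)


def top_lem_edges(local_ranking: RankingTable, seed: RegulatoryNetwork,
                  k_user: int) -> list[EdgeHypothesis]:
    """Seed edges plus the next K ranked edges, minus self-repression.

    The size of this list is also the worst-rank constant of the global
    edge ranking.
    """
    seed_keys = {e.key for e in seed.edges}
    out = [EdgeHypothesis.from_key(k) for k in seed_keys]
    extra = 0
    for key, _, _ in local_ranking.items:
        if extra >= k_user:
            break
        if key in seed_keys:
            continue
        e = EdgeHypothesis.from_key(key)
        extra += 1  # consume a user slot even if the edge is then removed
        if e.is_self_repression:
            log.info("self-repressing candidate %s removed", key)
            continue
        out.append(e)
    dropped = [e for e in out if e.is_self_repression]
    out = [e for e in out if not e.is_self_repression]
    if dropped:
        log.warning("removed %d self-repressing seed edges", len(dropped))
    return sorted(out)


@dataclass
class SampleRecord:
    network: RegulatoryNetwork
    n_regions: int


@dataclass
class SamplerStats:
    attempts: int = 0
    rejections: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejections[reason] = self.rejections.get(reason, 0) + 1


MOVES = ("add_node", "add_edge", "drop_node", "drop_edge")


def sample_networks(seed: RegulatoryNetwork,
                    candidates: list[EdgeHypothesis],
                    cfg: NetworkFindingConfig,
                    rng: np.random.Generator,
                    essential_only: bool = True,
                    ) -> tuple[list[SampleRecord], SamplerStats]:
    """Draw ``cfg.sample_size`` unique eligible networks around the seed."""
    cfg.validate()
    if any(e.is_self_repression for e in candidates):
        raise ValueError("candidate edges must not contain self-repression")
    probs = np.array([cfg.prob_add_node, cfg.prob_add_edge,
                      cfg.prob_drop_node, cfg.prob_drop_edge])
    stats = SamplerStats()
    accepted: dict[str, SampleRecord] = {}
    seed_edges = set(seed.edges)
    cand_set = set(candidates)

    while len(accepted) < cfg.sample_size:
        if stats.attempts >= cfg.attempt_budget:
            rate = len(accepted) / max(stats.attempts, 1)
            raise RuntimeError(
                f"sampler produced {len(accepted)}/{cfg.sample_size} networks in "
                f"{stats.attempts} attempts (acceptance {rate:.2%}); "
                "revise the search hyperparameters")
        stats.attempts += 1
        edges = set(seed_edges)
        n_ops = int(rng.integers(cfg.min_operations, cfg.max_operations + 1))
        ok = True
        for _ in range(n_ops):
            if not _apply_move(edges, cand_set, probs, rng):
                ok = False
                break
        if not ok:
            stats.reject("stalled")
            continue
        if not edges:
            stats.reject("empty")
            continue
        net = RegulatoryNetwork.from_edges(sorted(edges))
        if net.has_self_repression():
            stats.reject("self_repression")
            continue
        if not net.is_strongly_connected():
            stats.reject("not_strongly_connected")
            continue
        try:
            n_regions = count_parameter_regions(
                net, essential_only, cap=cfg.region_cap,
                max_in_degree=cfg.max_in_degree)
        except RegionCapacityError:
            stats.reject("region_cap")
            continue
        key = net.canonical()
        if key in accepted:
            stats.reject("duplicate")
            continue
        accepted[key] = SampleRecord(net, n_regions)
    return list(accepted.values()), stats


def write_sample_manifest(records: list[SampleRecord], stats: SamplerStats,
                          path) -> None:
    """Manifest of accepted networks plus the sampler's rejection tallies."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("network_id\tnetwork\tn_regions\taccepted\n")
        for i, rec in enumerate(records):
            one_line = "; ".join(rec.network.serialize().strip().splitlines())
            fh.write(f"net{i:05d}\t{one_line}\t{rec.n_regions}\t1\n")
        fh.write(f"# attempts: {stats.attempts}\n")
        for reason, count in sorted(stats.rejections.items()):
            fh.write(f"# rejected {reason}: {count}\n")


def _apply_move(edges: set[EdgeHypothesis], candidates: set[EdgeHypothesis],
                probs: np.ndarray, rng: np.random.Generator,
                max_redraws: int = 8) -> bool:
    """Apply one random move in place; False when every redraw stalls."""
    nodes = {e.source for e in edges} | {e.target for e in edges}
    cand_nodes = {e.source for e in candidates} | {e.target for e in candidates}
    # one edge per ordered pair: the two signed variants are exclusive
    present_pairs = {(e.source, e.target) for e in edges}
    unused = sorted(e for e in candidates - edges
                    if (e.source, e.target) not in present_pairs)
    for _ in range(max_redraws):
        move = MOVES[int(rng.choice(4, p=probs))]
        if move == "add_edge":
            pool = [e for e in unused
                    if e.source in nodes and e.target in nodes] or unused
            if not pool:
                continue
            edges.add(pool[int(rng.integers(len(pool)))])
            return True
        if move == "add_node":
            new_nodes = sorted(cand_nodes - nodes)
            if not new_nodes:
                continue
            v = new_nodes[int(rng.integers(len(new_nodes)))]
            incident = [e for e in unused if v in (e.source, e.target)]
            if not incident:
                continue
            # prefer connecting the node in both directions when possible
            into = [e for e in incident if e.target == v]
            outof = [e for e in incident if e.source == v]
            if into and outof:
                edges.add(into[int(rng.integers(len(into)))])
                edges.add(outof[int(rng.integers(len(outof)))])
            else:
                edges.add(incident[int(rng.integers(len(incident)))])
            return True
        if move == "drop_edge":
            droppable = sorted(edges)
            if not droppable:
                continue
            edges.discard(droppable[int(rng.integers(len(droppable)))])
            return True
        if move == "drop_node":
            if len(nodes) <= 1:
                continue
            v = sorted(nodes)[int(rng.integers(len(nodes)))]
            for e in [e for e in edges if v in (e.source, e.target)]:
                edges.discard(e)
            return True
    return False
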