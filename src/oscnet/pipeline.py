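"""End-to-end orchestration of the three inference stages.

Stage 1 (optional) ranks genes by periodicity/amplitude and truncates to
the most promising candidates.  Stage 2 ranks all allowed pairwise
regulation hypotheses by Bayesian model evidence.  Stage 3 samples
strongly connected networks around the seed induced by the strongest
edges, scores each network's combinatorial dynamics against the data's
extremum order, and aggregates the top networks into global edge and node
rankings.  Every stochastic step draws from a generator seeded by the
run's master seed, so a full run is reproducible bit-for-bit at the level
of its reported tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .core import GeneAnnotation, RankingTable, write_ranking
from .edgefind import (EdgeModelResult, local_edge_ranking, node_participation,
                       run_edge_finding)
from .events import DataGraph, periodic_data_graph
from .hill import FitHyperparams
from .match import score_network
from .netrank import (NetworkScore, TopNetworkCriteria, compare_rankings,
                      edge_prevalence, global_edge_ranking,
                      select_top_networks)
from .netspec import RegulatoryNetwork
from .nodefind import rank_nodes, score_nodes
from .search import sample_networks, seed_network, top_lem_edges
from .timeseries import TimeSeriesSet, align_replicates

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage receives an empty upstream selection."""


@dataclass
class PipelineResult:
    node_ranking: RankingTable | None
    edge_results: list[EdgeModelResult]
    local_edge_ranking: RankingTable
    local_node_ranking: RankingTable
    seed: RegulatoryNetwork
    candidate_edges: list
    network_scores: list[NetworkScore]
    top_networks: list[NetworkScore]
    global_edge_ranking: RankingTable
    global_node_ranking: RankingTable
    comparison: list
    data_graphs: dict[str, DataGraph] = field(default_factory=dict)
    node_scores: list = field(default_factory=list)
    sample_records: list = field(default_factory=list)
    sampler_stats: object = None


def run_pipeline(config: PipelineConfig,
                 datasets: list[TimeSeriesSet],
                 annotations: dict[str, GeneAnnotation] | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run node -> edge -> network finding on replicate datasets."""
    config.validate()
    if not datasets:
        raise PipelineError("no input datasets")
    replicates = align_replicates(datasets)
    dropped = set(datasets[0].gene_names) - set(replicates[0].gene_names)
    if dropped:
        log.warning("genes missing from some replicate dropped: %s",
                    ",".join(sorted(dropped)))
    rng = np.random.default_rng(config.seed)

    # ---- stage 1: node finding (skippable) ------------------------------
    node_ranking = None
    node_scores: list = []
    if config.node_finding.enabled:
        node_scores = score_nodes(replicates[0], config.node_finding.periods,
                                  config.node_finding.n_random_curves, rng,
                                  config.node_finding.n_phases)
        node_ranking = rank_nodes(node_scores, config.node_finding.top_k)
        keep = node_ranking.keys
        if not keep:
            raise PipelineError("node finding selected no genes")
        replicates = [rep.subset(keep) for rep in replicates]
    else:
        log.info("node finding skipped by configuration")

    # ---- stage 2: edge finding ------------------------------------------
    hyper = FitHyperparams(
        n_iterations=config.edge_finding.n_iterations,
        temperature=config.edge_finding.temperature,
        step_size=config.edge_finding.step_size,
        interval=config.edge_finding.interval,
        local_optimizer=config.edge_finding.local_optimizer,
    )
    edge_results = run_edge_finding(replicates, hyper, rng, annotations)
    if not edge_results:
        raise PipelineError("edge finding produced no models")
    local_rank = local_edge_ranking(edge_results)

    # ---- stage 3: network finding ---------------------------------------
    nf = config.network_finding
    seed = seed_network(local_rank, nf.pld_threshold)
    candidates = top_lem_edges(local_rank, seed, nf.n_user_edges)
    if not candidates:
        raise PipelineError("no candidate edges above the ranking cutoff")
    cand_keys = [e.key for e in candidates]
    nodes = list(replicates[0].gene_names)
    local_node_rank = node_participation(local_rank, nodes, cand_keys)

    data_graphs = {rep.replicate_id: periodic_data_graph(rep, nf.noise_level)
                   for rep in replicates}

    records, stats = sample_networks(seed, candidates, nf, rng)
    log.info("sampler: %d attempts, rejections %s", stats.attempts,
             stats.rejections)
    net_scores = []
    for i, rec in enumerate(records):
        dyn = score_network(rec.network, data_graphs, cap=nf.region_cap,
                            max_in_degree=nf.max_in_degree)
        net_scores.append(NetworkScore.from_dynamics(f"net{i:05d}", rec.network, dyn))

    criteria = TopNetworkCriteria(
        oscillation_min=config.top_networks.oscillation_min,
        oscillation_max=config.top_networks.oscillation_max,
        pattern_match_min=config.top_networks.pattern_match_min,
        require_all_replicates=config.top_networks.require_all_replicates,
    )
    top = select_top_networks(net_scores, criteria)
    prevalences = edge_prevalence(top, candidates)
    global_rank = global_edge_ranking(prevalences, local_rank)
    global_node_rank = node_participation(global_rank, nodes, cand_keys)
    comparison = compare_rankings(local_rank, global_rank, nodes, cand_keys)

    result = PipelineResult(
        node_ranking=node_ranking,
        node_scores=node_scores,
        edge_results=edge_results,
        local_edge_ranking=local_rank,
        local_node_ranking=local_node_rank,
        seed=seed,
        candidate_edges=candidates,
        network_scores=net_scores,
        top_networks=top,
        global_edge_ranking=global_rank,
        global_node_ranking=global_node_rank,
        comparison=comparison,
        data_graphs=data_graphs,
        sample_records=records,
        sampler_stats=stats,
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if result.node_ranking is not None:
        from .nodefind import write_node_ranking
        write_node_ranking(result.node_ranking, result.node_scores,
                           out_dir / "node_ranking.tsv")
    write_ranking(result.local_edge_ranking, out_dir / "local_edge_ranking.tsv",
                  "edge")
    write_ranking(result.local_node_ranking, out_dir / "local_node_ranking.tsv",
                  "gene")
    write_ranking(result.global_edge_ranking, out_dir / "global_edge_ranking.tsv",
                  "edge")
    write_ranking(result.global_node_ranking, out_dir / "global_node_ranking.tsv",
                  "gene")
    with open(out_dir / "network_scores.tsv", "w", encoding="utf-8") as fh:
        fh.write("network_id\tn_regions\toscillation_score\tpattern_match_score\ttop\n")
        top_ids = {s.network_id for s in result.top_networks}
        for s in result.network_scores:
            fh.write(f"{s.network_id}\t{s.n_regions}\t{s.oscillation_score:.6g}"
                     f"\t{s.pattern_match_score:.6g}\t{int(s.network_id in top_ids)}\n")
    with open(out_dir / "top_networks.txt", "w", encoding="utf-8") as fh:
        for s in result.top_networks:
            fh.write(f"# {s.network_id}\n{s.network.serialize()}\n")
    if result.sampler_stats is not None:
        from .search import write_sample_manifest
        write_sample_manifest(result.sample_records, result.sampler_stats,
                              out_dir / "sample_manifest.tsv")
    from .netrank import write_comparison
    write_comparison(result.comparison, out_dir / "node_comparison.tsv")
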