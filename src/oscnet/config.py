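"""Pipeline configuration.

Defaults mirror the benchmark hyperparameters used throughout the package:
mean-squared-error loss with ten basin-hopping iterations at temperature 1,
step size 0.5 and adaptation interval 10 for edge fitting; a posterior
threshold of 0.98 for the seed network, 40 extra candidate edges, 2-10
sampling operations, add-node/add-edge/drop-node/drop-edge probabilities
(0.1, 0.9, 0.0, 0.0), 0% extremum noise, 2000 sampled networks and a
3000-parameter-region cap for network finding.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class NodeFindingConfig:
    enabled: bool = True
    n_random_curves: int = 1000
    periods: list[float] = field(default_factory=list)  # mandatory when enabled
    n_phases: int | None = None   # defaults to the number of sample times
    top_k: int | None = None      # genes passed on to edge finding

    def validate(self) -> None:
        if self.enabled and not self.periods:
            raise ValueError("node finding requires an explicit period list")
        if self.n_random_curves < 1:
            raise ValueError("n_random_curves must be >= 1")


@dataclass
class EdgeFindingConfig:
    loss: str = "MSE"
    local_optimizer: str = "L-BFGS-B"
    n_iterations: int = 10
    temperature: float = 1.0
    step_size: float = 0.5
    interval: int = 10

    def validate(self) -> None:
        if self.loss.upper() != "MSE":
            raise ValueError("only MSE loss is supported")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class NetworkFindingConfig:
    pld_threshold: float = 0.98
    n_user_edges: int = 40
    min_operations: int = 2
    max_operations: int = 10
    noise_level: float = 0.0
    prob_add_node: float = 0.1
    prob_add_edge: float = 0.9
    prob_drop_node: float = 0.0
    prob_drop_edge: float = 0.0
    sample_size: int = 2000
    region_cap: int = 3000
    max_in_degree: int = 4
    attempt_budget: int = 200000

    def validate(self) -> None:
        probs = (self.prob_add_node, self.prob_add_edge,
                 self.prob_drop_node, self.prob_drop_edge)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("move probabilities must be in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("move probabilities must sum to 1")
        if self.min_operations > self.max_operations or self.min_operations < 1:
            raise ValueError("operation range must be a nonempty positive interval")
        if self.region_cap <= 0 or self.sample_size <= 0:
            raise ValueError("caps must be positive")
        if not 0.0 <= self.noise_level < 1.0:
            raise ValueError("noise level is a fraction of trace range in [0, 1)")


@dataclass
class TopNetworkConfig:
    oscillation_min: float = 1.0
    oscillation_max: float = 1.0
    pattern_match_min: float = 0.5
    require_all_replicates: bool = False

    def validate(self) -> None:
        if self.oscillation_min > self.oscillation_max:
            raise ValueError("oscillation window has lo > hi")


@dataclass
class PipelineConfig:
    node_finding: NodeFindingConfig = field(default_factory=NodeFindingConfig)
    edge_finding: EdgeFindingConfig = field(default_factory=EdgeFindingConfig)
    network_finding: NetworkFindingConfig = field(default_factory=NetworkFindingConfig)
    top_networks: TopNetworkConfig = field(default_factory=TopNetworkConfig)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.node_finding.validate()
        self.edge_finding.validate()
        self.network_finding.validate()
        self.top_networks.validate()
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(typ, sub):
            known = {f.name for f in dataclasses.fields(typ)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown {typ.__name__} keys: {sorted(unknown)}")
            return typ(**sub)

        cfg = cls(
            node_finding=build(NodeFindingConfig, d.get("node_finding", {})),
            edge_finding=build(EdgeFindingConfig, d.get("edge_finding", {})),
            network_finding=build(NetworkFindingConfig, d.get("network_finding", {})),
            top_networks=build(TopNetworkConfig, d.get("top_networks", {})),
            seed=int(d.get("seed", 0)),
        )
        return cfg.validate()

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
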