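"""Serializable pipeline configuration (YAML in, YAML out)."""
from __future__ import annotations

import dataclasses
from dataclasses import field
from pathlib import Path

import yaml

from .simulate import SimulationConfig

__all__ = ["PipelineConfig"]


@dataclasses.dataclass
class PipelineConfig:
    """Every numeric parameter and seed of an end-to-end run.

    A run's configuration is embedded in its output directory so results
    can be reproduced byte-for-byte from the YAML alone.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_hvg: int = 500
    network_hvg: int = 300
    pool_size: int = 20
    auroc_threshold: float = 0.6
    expressolog_threshold: float = 0.55
    expression_percentile: float = 10.0
    k: int = 10
    alpha: float = 0.05
    n_bulk_species: int = 7
    focal_species: str | None = None  # default: the simulation's focal lineage
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.simulation)
        d["simulation"]["divergent_gene_ids"] = list(self.simulation.divergent_gene_ids)
        d["simulation"]["absent_types"] = {
            int(k): list(v) for k, v in self.simulation.absent_types.items()
        }
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        sim = dict(sim)
        if "divergent_gene_ids" in sim:
            sim["divergent_gene_ids"] = tuple(sim["divergent_gene_ids"])
        if "absent_types" in sim:
            sim["absent_types"] = {int(k): tuple(v) for k, v in sim["absent_types"].items()}
        return cls(simulation=SimulationConfig(**sim), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
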