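"""Synthetic multi-species single-nucleus data with known ground truth.

The generator emulates the statistical structure the comparative pipeline
assumes: several species sharing a set of latent cell types, 1:1
orthologues whose cell-type mean-expression profiles are correlated across
species at a tunable level, planted co-expression modules, and a small set
of planted genes whose expression profile and co-expression neighbourhood
are rewired in exactly one designated (focal) lineage.

Counts are negative binomial around latent cell-type x gene means; the
cross-species profile correlation is induced on the log latent means
through a shared plus an independent Gaussian component, which gives
direct control over the expected profile correlation.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import CellPopulationDataset, OrthologyMap
from .networks import CoexpressionNetwork, celltype_network

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "simulate_dataset",
    "simulate_bulk_networks",
]

PRIMATE_NAMES = ("human", "chimp", "gorilla", "macaque", "marmoset")
BRAIN_CLASSES = ("ExN", "InN", "NonN")


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic multi-species experiment.

    Defaults are scaled-down study conditions: five primate-like species,
    21 shared cell types in three classes, negative-binomial counts with a
    common dispersion, high but imperfect cross-species profile
    conservation, and ten planted 12-gene co-expression modules.
    """

    n_species: int = 5
    n_cell_types: int = 21
    cells_per_type: int = 50
    n_genes: int = 2000
    orthology_fraction: float = 1.0
    profile_conservation: float = 0.95
    coexpr_module_count: int = 10
    module_size: int = 12
    divergent_gene_ids: tuple[str, ...] = ()
    divergent_class: str = "ExN"
    focal_species_index: int = 0
    n_classes: int = 3
    dispersion: float = 0.3
    library_size_mean: float = 5000.0
    profile_sd: float = 1.5
    module_strength: float = 1.0
    divergence_mode: str = "reverse"  # or "cyclic"
    absent_types: Mapping[int, tuple[int, ...]] = field(default_factory=dict)
    seed: int = 0

    # ------------------------------------------------------------- derived
    @property
    def species_names(self) -> tuple[str, ...]:
        if self.n_species <= len(PRIMATE_NAMES):
            return PRIMATE_NAMES[: self.n_species]
        return tuple(f"sp{i}" for i in range(self.n_species))

    @property
    def class_names(self) -> tuple[str, ...]:
        if self.n_classes == 3:
            return BRAIN_CLASSES
        return tuple(f"class{i}" for i in range(self.n_classes))

    @property
    def n_orthologues(self) -> int:
        return int(round(self.orthology_fraction * self.n_genes))

    @property
    def ortho_gene_ids(self) -> pd.Index:
        return pd.Index([f"g{i:05d}" for i in range(self.n_orthologues)])

    def class_of_type(self, t: int) -> str:
        return self.class_names[t % self.n_classes]

    def module_of_gene(self) -> np.ndarray:
        """Module index per orthologous gene (-1 outside any module)."""
        mem = np.full(self.n_orthologues, -1, dtype=int)
        for m in range(self.coexpr_module_count):
            mem[m * self.module_size: (m + 1) * self.module_size] = m
        return mem

    # ---------------------------------------------------------- validation
    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        if self.n_cell_types < 1:
            raise ConfigurationError("n_cell_types must be >= 1")
        if self.cells_per_type < 1:
            raise ConfigurationError("cells_per_type must be >= 1")
        if self.n_genes < self.module_size * self.coexpr_module_count:
            raise ConfigurationError(
                "n_genes must be >= module_size * coexpr_module_count "
                f"({self.n_genes} < {self.module_size * self.coexpr_module_count})"
            )
        if not 0.0 <= self.orthology_fraction <= 1.0:
            raise ConfigurationError("orthology_fraction must lie in [0, 1]")
        if not -1.0 <= self.profile_conservation <= 1.0:
            raise ConfigurationError("profile_conservation must lie in [-1, 1]")
        if self.profile_conservation < 0 and self.n_species > 2:
            raise ConfigurationError(
                "profile_conservation < 0 is only consistent for n_species == 2"
            )
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if not 0 <= self.focal_species_index < self.n_species:
            raise ConfigurationError("focal_species_index outside species range")
        if self.divergent_class not in self.class_names:
            raise ConfigurationError(
                f"divergent_class {self.divergent_class!r} not among classes {self.class_names}"
            )
        if self.divergence_mode not in ("reverse", "cyclic"):
            raise ConfigurationError("divergence_mode must be 'reverse' or 'cyclic'")
        universe = set(self.ortho_gene_ids)
        bad = [g for g in self.divergent_gene_ids if g not in universe]
        if bad:
            raise ConfigurationError(
                f"divergent_gene_ids outside the orthologue universe: {bad[:5]}"
            )
        if self.divergent_gene_ids:
            if self.coexpr_module_count < 2:
                raise ConfigurationError(
                    "coexpr_module_count must be >= 2 to rewire divergent neighbourhoods"
                )
            mem = self.module_of_gene()
            pos = self.ortho_gene_ids.get_indexer(list(self.divergent_gene_ids))
            outside = [g for g, m in zip(self.divergent_gene_ids, mem[pos]) if m < 0]
            if outside:
                raise ConfigurationError(
                    f"divergent_gene_ids must belong to a planted module: {outside[:5]}"
                )
        for s_idx, types in self.absent_types.items():
            if not 0 <= s_idx < self.n_species:
                raise ConfigurationError(f"absent_types species index {s_idx} out of range")
            if any(not 0 <= t < self.n_cell_types for t in types):
                raise ConfigurationError("absent_types cell-type index out of range")


@dataclasses.dataclass
class GroundTruth:
    """Planted structure the pipeline is expected to recover."""

    true_cluster_homology: dict  # (species, cluster) -> latent cell-type index
    true_divergent_genes: frozenset
    true_module_membership: dict  # species -> {gene -> module index}
    focal_species: str
    divergent_class: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_cluster_homology": [
                {"species": s, "cluster": c, "cell_type": int(t)}
                for (s, c), t in sorted(self.true_cluster_homology.items())
            ],
            "true_divergent_genes": sorted(self.true_divergent_genes),
            "true_module_membership": {
                s: {g: int(m) for g, m in mm.items()} for s, mm in self.true_module_membership.items()
            },
            "focal_species": self.focal_species,
            "divergent_class": self.divergent_class,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            {(r["species"], r["cluster"]): r["cell_type"] for r in d["true_cluster_homology"]},
            frozenset(d["true_divergent_genes"]),
            d["true_module_membership"],
            d["focal_species"],
            d["divergent_class"],
        )


def _rewire_profile(v: np.ndarray, mode: str) -> np.ndarray:
    """Permute a gene's within-class cell-type means.

    ``reverse`` assigns the largest mean to the type that had the smallest
    (rank-reversing permutation): it preserves the multiset of expression
    magnitudes while forcing a strongly negative profile correlation.
    ``cyclic`` rolls the means by one type, a milder decorrelation.
    """
    if mode == "cyclic":
        return np.roll(v, 1)
    order = np.argsort(v, kind="stable")
    out = np.empty_like(v)
    out[order] = v[order[::-1]]
    return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[CellPopulationDataset], OrthologyMap, GroundTruth]:
    """Draw one single-nucleus-like dataset per species.

    Returns the per-species datasets, the 1:1 orthology map over the shared
    genes, and the planted :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_ortho = config.n_orthologues
    n_private = config.n_genes - n_ortho
    ortho_ids = config.ortho_gene_ids
    species = config.species_names
    n_types = config.n_cell_types
    types = np.arange(n_types)
    class_of = np.array([config.class_of_type(t) for t in types])
    rho = abs(config.profile_conservation)
    a = np.sqrt(rho)

    # latent log-means: shared baseline + shared/species-specific profile parts
    base_ortho = rng.normal(0.0, 1.2, size=n_ortho)
    z_shared = rng.normal(0.0, config.profile_sd, size=(n_ortho, n_types))

    base_mem = config.module_of_gene()
    divergent_pos = ortho_ids.get_indexer(list(config.divergent_gene_ids))
    focal = species[config.focal_species_index]

    datasets: list[CellPopulationDataset] = []
    homology: dict = {}
    module_membership: dict = {}
    for s_idx, sp_name in enumerate(species):
        eps = rng.normal(0.0, config.profile_sd, size=(n_ortho, n_types))
        sign = -1.0 if (config.profile_conservation < 0 and s_idx > 0) else 1.0
        e = sign * a * z_shared + np.sqrt(1.0 - rho) * eps

        mem = base_mem.copy()
        if sp_name == focal:
            for g_pos in divergent_pos:
                cls_cols = np.flatnonzero(class_of == config.divergent_class)
                e[g_pos, cls_cols] = _rewire_profile(e[g_pos, cls_cols], config.divergence_mode)
                mem[g_pos] = (base_mem[g_pos] + 1) % config.coexpr_module_count

        base_priv = rng.normal(0.0, 1.2, size=n_private)
        e_priv = rng.normal(0.0, config.profile_sd, size=(n_private, n_types))
        log_mu = np.vstack(
            [
                base_ortho[:, None] + e,
                base_priv[:, None] + e_priv,
            ]
        )
        gene_ids = ortho_ids.append(pd.Index([f"{sp_name}_p{i:04d}" for i in range(n_private)]))

        loadings = np.zeros((config.n_genes, max(config.coexpr_module_count, 1)))
        in_module = np.flatnonzero(mem >= 0)
        loadings[in_module, mem[in_module]] = 1.0

        absent = set(config.absent_types.get(s_idx, ()))
        blocks, meta_rows = [], []
        for t in types:
            if t in absent:
                continue
            n_c = config.cells_per_type
            factors = rng.normal(0.0, 1.0, size=(loadings.shape[1], n_c))
            log_rate = log_mu[:, t][:, None] + config.module_strength * (loadings @ factors)
            rate = np.exp(log_rate)
            p = rate / rate.sum(axis=0, keepdims=True)
            lib = rng.gamma(10.0, config.library_size_mean / 10.0, size=n_c)
            mu = p * lib[None, :]
            if config.dispersion > 1e-12:
                lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mu)
                counts_t = rng.poisson(lam)
            else:
                counts_t = rng.poisson(mu)
            blocks.append(counts_t)
            cluster = f"{sp_name}_c{t:02d}"
            homology[(sp_name, cluster)] = int(t)
            for c in range(n_c):
                meta_rows.append(
                    {
                        "species": sp_name,
                        "donor": f"{sp_name}_d{c % 2}",
                        "cluster": cluster,
                        "class_label": class_of[t],
                        "subclass": f"SC{t // 2:02d}",
                    }
                )
        counts = np.concatenate(blocks, axis=1)
        meta = pd.DataFrame(meta_rows)
        datasets.append(CellPopulationDataset(counts.astype(np.int64), gene_ids, meta, sp_name))
        module_membership[sp_name] = {
            str(ortho_ids[g]): int(mem[g]) for g in np.flatnonzero(mem >= 0)
        }

    orthology = OrthologyMap.identity(species, list(ortho_ids), provenance="simulated")
    truth = GroundTruth(
        true_cluster_homology=homology,
        true_divergent_genes=frozenset(config.divergent_gene_ids),
        true_module_membership=module_membership,
        focal_species=focal,
        divergent_class=config.divergent_class,
    )
    return datasets, orthology, truth


def simulate_bulk_networks(
    config: SimulationConfig,
    n_extra_species: int,
    n_samples: int = 200,
    module_corr_strength: float = 3.0,
    seed: int | None = None,
) -> list[CoexpressionNetwork]:
    """Rank-standardized aggregate co-expression networks for the focal
    species plus ``n_extra_species`` conserved outgroup species.

    Every network carries the planted module structure over the orthologue
    universe; the planted divergent genes have their module membership
    reassigned in the focal lineage only, so their top co-expression
    partners there are disjoint from their partners everywhere else.
    """
    config.validate()
    if n_extra_species < 2:
        raise ValueError(
            "n_extra_species must be >= 2: the divergence screen needs a multi-species background"
        )
    rng = np.random.default_rng([config.seed if seed is None else seed, 0x5EED])
    ortho_ids = config.ortho_gene_ids
    base_mem = config.module_of_gene()
    divergent_pos = ortho_ids.get_indexer(list(config.divergent_gene_ids))
    focal = config.species_names[config.focal_species_index]

    names = [focal] + [f"outgroup{i + 1}" for i in range(n_extra_species)]
    networks = []
    for name in names:
        mem = base_mem.copy()
        if name == focal:
            for g_pos in divergent_pos:
                mem[g_pos] = (base_mem[g_pos] + 1) % config.coexpr_module_count
        loadings = np.zeros((len(ortho_ids), max(config.coexpr_module_count, 1)))
        in_module = np.flatnonzero(mem >= 0)
        loadings[in_module, mem[in_module]] = 1.0
        factors = rng.normal(0.0, 1.0, size=(loadings.shape[1], n_samples))
        x = module_corr_strength * (loadings @ factors) + rng.normal(0.0, 1.0, size=(len(ortho_ids), n_samples))
        net = celltype_network(x, ortho_ids)
        net.species = name
        net.provenance = [f"simulated-bulk:{name}"]
        networks.append(net)
    return networks
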