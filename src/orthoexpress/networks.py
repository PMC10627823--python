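"""Aggregate rank-standardized co-expression networks.

A cell-type network is the Spearman correlation of highly variable genes
across pseudobulk pools of nuclei, rank-standardized to [0, 1] over all
gene pairs; the species-level network is the element-wise mean of its
cell-type networks.  The same aggregation operator applies to networks
built from bulk expression samples.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datasets import CellPopulationDataset

__all__ = [
    "CoexpressionNetwork",
    "pool_nuclei",
    "celltype_network",
    "aggregate_networks",
    "build_species_network",
    "read_dense_network",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class CoexpressionNetwork:
    """Symmetric gene x gene matrix of rank-standardized co-expression.

    Off-diagonal values lie in [0, 1]; the diagonal is fixed to 1 and is
    excluded from ranking (recorded here as the package convention).
    """

    matrix: np.ndarray
    gene_ids: pd.Index
    species: str | None = None
    provenance: list[str] = dataclasses.field(default_factory=list)
    n_samples_per_component: list[int] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        n = len(self.gene_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({n}, {n})")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset(self, genes: Sequence[str]) -> "CoexpressionNetwork":
        idx = self.gene_ids.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = list(pd.Index(genes)[idx < 0][:5])
            raise KeyError(f"genes absent from network: {missing}")
        return CoexpressionNetwork(
            self.matrix[np.ix_(idx, idx)], pd.Index(genes), self.species,
            list(self.provenance), list(self.n_samples_per_component),
        )

    def rename_genes(self, mapping: pd.Series) -> "CoexpressionNetwork":
        keep = np.flatnonzero(self.gene_ids.isin(mapping.index))
        new_ids = pd.Index(mapping.loc[self.gene_ids[keep]].to_numpy())
        return CoexpressionNetwork(
            self.matrix[np.ix_(keep, keep)], new_ids, self.species,
            list(self.provenance), list(self.n_samples_per_component),
        )

    # -------------------------------------------------------------------- io
    def write_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("matrix", data=self.matrix, compression="gzip")
            f.create_dataset("genes", data=np.array(self.gene_ids, dtype="S"))
            f.attrs["species"] = self.species or ""
            f.attrs["provenance"] = ";".join(self.provenance)

    @classmethod
    def read_h5(cls, path: str | Path) -> "CoexpressionNetwork":
        with h5py.File(path, "r") as f:
            matrix = f["matrix"][:]
            genes = pd.Index([g.decode() for g in f["genes"][:]])
            species = f.attrs.get("species") or None
            prov = [p for p in str(f.attrs.get("provenance", "")).split(";") if p]
        return cls(matrix, genes, species, prov)

    def to_edge_list(self, path: str | Path) -> None:
        iu = np.triu_indices(self.n_genes, k=1)
        pd.DataFrame(
            {
                "gene_a": self.gene_ids[iu[0]],
                "gene_b": self.gene_ids[iu[1]],
                "weight": self.matrix[iu],
            }
        ).to_csv(path, sep="\t", index=False)


def read_dense_network(
    matrix_path: str | Path, genes_path: str | Path, species: str | None = None
) -> CoexpressionNetwork:
    """Read an externally supplied aggregate network: a dense whitespace- or
    tab-delimited matrix plus a one-column gene list."""
    matrix = np.loadtxt(matrix_path)
    genes = pd.Index(pd.read_csv(genes_path, sep="\t", header=None)[0])
    return CoexpressionNetwork(matrix, genes, species, provenance=[str(matrix_path)])


def pool_nuclei(
    dataset: CellPopulationDataset,
    cell_type: str,
    pool_size: int = 20,
    seed: int = 0,
    column: str = "cluster",
) -> np.ndarray | None:
    """Sum counts over disjoint random pools of ``pool_size`` nuclei.

    Nuclei of the requested cell type are randomly partitioned (seeded)
    into floor(n / pool_size) pools; remainder nuclei are dropped so every
    pool has identical depth.  Returns a genes x pools matrix, or None
    (with a warning) when fewer than two pools can be formed.
    """
    cells = np.flatnonzero((dataset.cell_meta[column] == cell_type).to_numpy())
    n_pools = len(cells) // pool_size
    if n_pools < 2:
        log.warning(
            "cell type %r skipped: %d nuclei support %d pool(s) of %d",
            cell_type, len(cells), n_pools, pool_size,
        )
        return None
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cells)[: n_pools * pool_size]
    x = dataset.dense_counts()[:, perm]
    return x.reshape(dataset.n_genes, n_pools, pool_size).sum(axis=2)


def _rank_standardize(corr: np.ndarray) -> np.ndarray:
    """Map correlations to [0, 1] by ranking all upper-triangle pairs.

    Undefined correlations (zero-variance genes) take the median rank,
    i.e. exactly 0.5 after standardization; ties get mid-ranks.
    """
    n = corr.shape[0]
    out = np.full((n, n), 0.5)
    iu = np.triu_indices(n, k=1)
    vals = corr[iu]
    finite = np.isfinite(vals)
    std = np.full(vals.shape, 0.5)
    n_f = int(finite.sum())
    if n_f >= 2:
        std[finite] = (rankdata(vals[finite]) - 1.0) / (n_f - 1.0)
    elif n_f == 1:
        std[finite] = 0.5
    out[iu] = std
    out.T[iu] = std
    np.fill_diagonal(out, 1.0)
    return out


def celltype_network(
    pools: np.ndarray | pd.DataFrame, gene_ids: Sequence[str] | None = None
) -> CoexpressionNetwork:
    """Spearman co-expression of all gene pairs across pseudobulk samples,
    rank-standardized to [0, 1].

    ``pools`` is genes x samples.  Genes constant across samples produce
    undefined correlations, which receive the median rank (0.5).
    """
    if isinstance(pools, pd.DataFrame):
        gene_ids = pools.index if gene_ids is None else gene_ids
        pools = pools.to_numpy(dtype=float)
    if gene_ids is None:
        raise ValueError("gene_ids required when pools is a bare array")
    pools = np.asarray(pools, dtype=float)
    if pools.shape[1] < 3:
        raise ValueError(f"need >= 3 pseudobulk samples, got {pools.shape[1]}")
    ranks = rankdata(pools, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    zero_var = norms == 0
    norms[zero_var] = 1.0
    z = centered / norms[:, None]
    corr = z @ z.T
    # Spearman values on few samples are highly tied; round away float
    # noise so theoretically equal correlations share a mid-rank
    corr = np.round(corr, 9)
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    net = CoexpressionNetwork(
        _rank_standardize(corr),
        pd.Index(gene_ids),
        n_samples_per_component=[pools.shape[1]],
    )
    return net


def aggregate_networks(components: Sequence[CoexpressionNetwork]) -> CoexpressionNetwork:
    """Element-wise mean of rank-standardized component networks."""
    if not components:
        raise ValueError("no component networks to aggregate")
    ref = components[0].gene_ids
    for c in components[1:]:
        if not ref.equals(c.gene_ids):
            diff = sorted(set(ref).symmetric_difference(c.gene_ids))
            raise ValueError(f"gene universe mismatch between components: {diff[:10]}")
    matrix = np.mean([c.matrix for c in components], axis=0)
    prov = [p for c in components for p in (c.provenance or ["unnamed"])]
    nspc = [n for c in components for n in (c.n_samples_per_component or [0])]
    return CoexpressionNetwork(matrix, ref, components[0].species, prov, nspc)


def build_species_network(
    dataset: CellPopulationDataset,
    hvg: Sequence[str],
    cell_types: Sequence[str] | None = None,
    pool_size: int = 20,
    seed: int = 0,
    column: str = "cluster",
) -> CoexpressionNetwork:
    """Aggregate of cell-type-specific networks for one species.

    For each cell type, nuclei are pooled into pseudobulk samples of
    ``pool_size``, a Spearman network over ``hvg`` is built, and the
    rank-standardized networks are averaged.  Cell types too small to form
    two pools are skipped with a warning.
    """
    ds = dataset.subset_genes(hvg)
    if cell_types is None:
        cell_types = sorted(ds.cell_meta[column].dropna().unique())
    comps = []
    for i, ct in enumerate(cell_types):
        pools = pool_nuclei(ds, ct, pool_size=pool_size, seed=seed + i, column=column)
        if pools is None or pools.shape[1] < 3:
            if pools is not None:
                log.warning("cell type %r skipped: fewer than 3 pools", ct)
            continue
        net = celltype_network(pools, ds.gene_ids)
        net.provenance = [f"{dataset.name}|{ct}"]
        comps.append(net)
    if not comps:
        raise ValueError("no cell type yielded enough pools to build a network")
    out = aggregate_networks(comps)
    out.species = dataset.species
    return out
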