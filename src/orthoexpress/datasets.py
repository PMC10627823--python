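"""Core data containers: per-species expression datasets and 1:1 orthology.

A :class:`CellPopulationDataset` is a genes x cells count matrix with
per-cell metadata (species, donor, within-species cluster, class and
subclass labels).  Orthology between species is carried by
:class:`OrthologyMap`, restricted to 1:1 relations.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["CellPopulationDataset", "OrthologyMap", "read_expression", "shared_orthologue_universe"]

META_COLUMNS = ("species", "donor", "cluster", "class_label", "subclass")


@dataclasses.dataclass
class CellPopulationDataset:
    """Genes x cells counts for one species plus per-cell annotations.

    Parameters
    ----------
    counts
        Non-negative genes x cells matrix (dense ndarray or scipy sparse).
    gene_ids
        Unique gene identifiers, one per row of ``counts``.
    cell_meta
        One row per cell with at least the columns in ``META_COLUMNS``.
    name
        Dataset label; defaults to the (single) species in ``cell_meta``.
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: pd.Index
    cell_meta: pd.DataFrame
    name: str | None = None

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        if self.gene_ids.has_duplicates:
            dup = self.gene_ids[self.gene_ids.duplicated()].unique()[:5]
            raise ValueError(f"gene_ids must be unique; duplicated e.g. {list(dup)}")
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"counts has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_meta):
            raise ValueError(
                f"counts has {n_cells} cells but metadata has {len(self.cell_meta)} rows"
            )
        missing = [c for c in ("species", "cluster") if c not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell_meta missing required columns: {missing}")
        if self.cell_meta["cluster"].isna().any():
            raise ValueError("every cell must carry a cluster label")
        if sp.issparse(self.counts):
            if self.counts.size and self.counts.min() < 0:
                raise ValueError("counts must be non-negative")
        elif self.counts.size and np.min(self.counts) < 0:
            raise ValueError("counts must be non-negative")
        if self.name is None:
            self.name = str(self.cell_meta["species"].iloc[0]) if len(self.cell_meta) else "dataset"
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    # ------------------------------------------------------------------ views
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def species(self) -> str:
        sp_ = self.cell_meta["species"].unique()
        if len(sp_) != 1:
            raise ValueError(f"dataset spans several species: {list(sp_)}")
        return str(sp_[0])

    def dense_counts(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def cpm(self) -> np.ndarray:
        """Per-cell counts-per-million (library-size normalized) matrix."""
        x = self.dense_counts()
        lib = x.sum(axis=0)
        lib[lib == 0] = 1.0
        return x / lib * 1e6

    def subset_genes(self, genes: Sequence[str]) -> "CellPopulationDataset":
        idx = self.gene_ids.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = list(pd.Index(genes)[idx < 0][:5])
            raise KeyError(f"genes absent from dataset {self.name}: {missing}")
        counts = self.counts[idx, :] if not sp.issparse(self.counts) else self.counts.tocsr()[idx, :]
        return CellPopulationDataset(counts, pd.Index(genes), self.cell_meta.copy(), self.name)

    def rename_genes(self, mapping: pd.Series) -> "CellPopulationDataset":
        """Rename gene ids via a Series old_id -> new_id, dropping unmapped genes."""
        keep = self.gene_ids.isin(mapping.index)
        counts = self.counts[np.flatnonzero(keep), :] if not sp.issparse(self.counts) else self.counts.tocsr()[np.flatnonzero(keep), :]
        new_ids = pd.Index(mapping.loc[self.gene_ids[keep]].to_numpy())
        return CellPopulationDataset(counts, new_ids, self.cell_meta.copy(), self.name)

    # -------------------------------------------------------------------- io
    def to_anndata(self):
        import anndata as ad

        x = self.counts.T.tocsr() if sp.issparse(self.counts) else np.asarray(self.counts).T
        obs = self.cell_meta.copy()
        obs.index = obs.index.astype(str)
        adata = ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=self.gene_ids))
        adata.uns["name"] = self.name
        return adata

    @classmethod
    def from_anndata(cls, adata, name: str | None = None) -> "CellPopulationDataset":
        x = adata.X
        counts = x.T.tocsr() if sp.issparse(x) else np.asarray(x).T
        return cls(counts, pd.Index(adata.var_names), adata.obs.reset_index(drop=True),
                   name or adata.uns.get("name"))

    def write_h5ad(self, path: str | Path) -> None:
        self.to_anndata().write_h5ad(Path(path))

    def write_mtx(self, prefix: str | Path) -> None:
        """Write `<prefix>.mtx`, `<prefix>.genes.tsv`, `<prefix>.cells.tsv`."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        mat = self.counts if sp.issparse(self.counts) else sp.csr_matrix(self.counts)
        mmwrite(str(prefix) + ".mtx", mat)
        pd.Series(self.gene_ids).to_csv(str(prefix) + ".genes.tsv", sep="\t", index=False, header=["gene_id"])
        self.cell_meta.to_csv(str(prefix) + ".cells.tsv", sep="\t", index=False)

    @classmethod
    def read_mtx(cls, prefix: str | Path, name: str | None = None) -> "CellPopulationDataset":
        prefix = str(prefix)
        counts = sp.csr_matrix(mmread(prefix + ".mtx"))
        genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")["gene_id"]
        meta = pd.read_csv(prefix + ".cells.tsv", sep="\t")
        if counts.shape[0] != len(genes) or counts.shape[1] != len(meta):
            raise ValueError(
                f"dimension mismatch reading {prefix}: matrix {counts.shape}, "
                f"{len(genes)} genes, {len(meta)} cells"
            )
        return cls(counts, pd.Index(genes), meta, name)


def read_expression(path: str | Path, format: str | None = None) -> CellPopulationDataset:
    """Read a dataset from ``<prefix>.mtx`` sidecar trio or an ``.h5ad`` file."""
    path = Path(path)
    fmt = format
    if fmt is None:
        fmt = "h5" if path.suffix in {".h5ad", ".h5"} else "mtx"
    if fmt == "h5":
        import anndata as ad

        return CellPopulationDataset.from_anndata(ad.read_h5ad(path))
    if fmt == "mtx":
        prefix = str(path)
        if prefix.endswith(".mtx"):
            prefix = prefix[: -len(".mtx")]
        return CellPopulationDataset.read_mtx(prefix)
    raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'h5'")


@dataclasses.dataclass
class OrthologyMap:
    """1:1 orthologue relations as (species_a, gene_a, species_b, gene_b) records."""

    table: pd.DataFrame
    provenance: str = ""

    REQUIRED = ("species_a", "gene_a", "species_b", "gene_b")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"orthology table missing columns {missing}")
        t = self.table
        for side in ("a", "b"):
            dup = t.duplicated(subset=[f"species_{side}", f"gene_{side}", f"species_{'b' if side == 'a' else 'a'}"])
            if dup.any():
                bad = t.loc[dup].iloc[0]
                raise ValueError(
                    "orthology is not 1:1: gene "
                    f"{bad[f'gene_{side}']} of {bad[f'species_{side}']} maps more than once"
                )

    @property
    def species(self) -> list[str]:
        return sorted(set(self.table["species_a"]) | set(self.table["species_b"]))

    def pair_map(self, species_a: str, species_b: str) -> pd.Series:
        """Series gene_a -> gene_b for one species pair (either stored direction)."""
        t = self.table
        fwd = t[(t["species_a"] == species_a) & (t["species_b"] == species_b)]
        rev = t[(t["species_a"] == species_b) & (t["species_b"] == species_a)]
        pairs = pd.concat(
            [
                fwd[["gene_a", "gene_b"]],
                rev.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})[["gene_a", "gene_b"]],
            ]
        ).drop_duplicates()
        if pairs.empty:
            raise KeyError(f"no orthology records for pair ({species_a}, {species_b})")
        return pd.Series(pairs["gene_b"].to_numpy(), index=pd.Index(pairs["gene_a"]))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "OrthologyMap":
        return cls(pd.read_csv(path, sep="\t"), provenance)

    @classmethod
    def identity(cls, species: Iterable[str], genes: Iterable[str], provenance: str = "shared-id") -> "OrthologyMap":
        """Orthology for gene universes that already share identifiers."""
        species = list(species)
        genes = list(genes)
        rows = []
        for i, sa in enumerate(species):
            for sb in species[i + 1:]:
                rows.append(pd.DataFrame({"species_a": sa, "gene_a": genes, "species_b": sb, "gene_b": genes}))
        return cls(pd.concat(rows, ignore_index=True), provenance)


def shared_orthologue_universe(
    datasets: Sequence[CellPopulationDataset], orthology: OrthologyMap
) -> list[CellPopulationDataset]:
    """Map every dataset into the reference namespace of the first dataset's
    species and subset all of them to the genes with 1:1 orthologues present
    in every dataset, in identical order."""
    ref = datasets[0].species
    mapped = [datasets[0]]
    universe = pd.Index(datasets[0].gene_ids)
    for ds in datasets[1:]:
        if ds.species == ref:
            mapped.append(ds)
            universe = universe.intersection(ds.gene_ids)
            continue
        to_ref = {v: k for k, v in orthology.pair_map(ref, ds.species).items()}
        renamed = ds.rename_genes(pd.Series(to_ref))
        mapped.append(renamed)
        universe = universe.intersection(renamed.gene_ids)
    if len(universe) == 0:
        raise ValueError("no shared 1:1 orthologues across the datasets")
    universe = pd.Index(sorted(universe))
    return [ds.subset_genes(universe) for ds in mapped]
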