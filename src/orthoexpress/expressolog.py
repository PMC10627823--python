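"""Expression-profile conservation of 1:1 orthologues (expressolog scores).

For a pair of species, every gene's pseudobulk profile (mean CPM across
shared consensus cell types) is Pearson-correlated against all N genes of
the other species.  The orthologue's correlation is ranked ascending among
the N candidates (mid-rank ties) and converted to an AUROC via
``(r - 1) / (N - 1)``; the expressolog score is the average of the two
directional AUROCs.  A score of 1 means the orthologue is the single best
expression match, 0.5 means uncorrelated profiles, 0 extreme divergence.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rank import auroc_from_rank, rank_cols, rank_rows
from .datasets import CellPopulationDataset, OrthologyMap
from .taxonomy import ConsensusTaxonomy

__all__ = [
    "PseudobulkProfile",
    "ExpressologTable",
    "pseudobulk",
    "auroc_from_rank",
    "expressolog_scores",
    "expressolog_scores_by_group",
    "isoform_self_prediction",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PseudobulkProfile:
    """Gene x cell-type matrix of normalized mean expression for one species."""

    matrix: pd.DataFrame  # genes x cell types, mean CPM
    species: str
    n_cells: pd.Series | None = None  # nuclei per cell type

    def __post_init__(self) -> None:
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("pseudobulk expression must be non-negative")

    @property
    def cell_types(self) -> pd.Index:
        return self.matrix.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    def to_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t")


@dataclasses.dataclass
class ExpressologTable:
    """Per-orthologue expressolog scores for one species pair (and group)."""

    table: pd.DataFrame  # index gene_a; columns gene_b, score_ab, score_ba, score
    species_a: str
    species_b: str
    n_genes: int
    group: str | None = None

    def __post_init__(self) -> None:
        s = self.table["score"]
        if ((s < -1e-9) | (s > 1 + 1e-9)).any():
            raise ValueError("expressolog scores must lie in [0, 1]")

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "species_pair", f"{self.species_a}|{self.species_b}")
        out.insert(1, "group", self.group or "all")
        out.to_csv(path, sep="\t")


def pseudobulk(
    dataset: CellPopulationDataset,
    taxonomy: ConsensusTaxonomy | None = None,
    min_cells: int = 1,
) -> PseudobulkProfile:
    """Mean per-cell CPM per consensus cell type.

    Cells are library-size normalized individually (CPM) before averaging,
    so the profile is invariant to per-cell sequencing depth.  When no
    taxonomy is given, within-species cluster labels are used directly.
    """
    if taxonomy is not None:
        node = dataset.name + "|" + dataset.cell_meta["cluster"].astype(str)
        groups = taxonomy.assignment.reindex(node.to_numpy()).to_numpy()
    else:
        groups = dataset.cell_meta["cluster"].astype(str).to_numpy()
    x = dataset.cpm()
    keep = ~pd.isna(groups)
    if not keep.any():
        raise ValueError("no cells mapped to any consensus cell type")
    cols, counts = {}, {}
    for g in sorted(pd.unique(groups[keep])):
        m = keep & (groups == g)
        if m.sum() < min_cells:
            continue
        cols[g] = x[:, m].mean(axis=1)
        counts[g] = int(m.sum())
    if not cols:
        raise ValueError("no consensus cell type reached the minimum cell count")
    matrix = pd.DataFrame(cols, index=dataset.gene_ids)
    return PseudobulkProfile(matrix, dataset.species, pd.Series(counts))


def _row_standardize(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = m - m.mean(axis=1, keepdims=True)
    norms = np.sqrt((c**2).sum(axis=1))
    degenerate = norms == 0
    norms[degenerate] = 1.0
    return c / norms[:, None], degenerate


def _aligned_matrices(
    profile_a: PseudobulkProfile,
    profile_b: PseudobulkProfile,
    orthology: OrthologyMap,
    cell_type_subset: Sequence[str] | None,
) -> tuple[np.ndarray, np.ndarray, pd.Index, pd.Index, pd.Index]:
    shared = profile_a.cell_types.intersection(profile_b.cell_types)
    if cell_type_subset is not None:
        shared = shared.intersection(pd.Index(cell_type_subset))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared cell types to correlate profiles, have {len(shared)}"
        )
    shared = shared.sort_values()
    amap = orthology.pair_map(profile_a.species, profile_b.species)
    genes_a = profile_a.gene_ids.intersection(amap.index)
    genes_a = genes_a[pd.Index(amap.loc[genes_a]).isin(profile_b.gene_ids)]
    if len(genes_a) < 2:
        raise ValueError("fewer than 2 orthologues shared between the profiles")
    genes_b = pd.Index(amap.loc[genes_a])
    a = profile_a.matrix.loc[genes_a, shared].to_numpy(dtype=float)
    b = profile_b.matrix.loc[genes_b, shared].to_numpy(dtype=float)
    return a, b, genes_a, genes_b, shared


def expressolog_scores(
    profile_a: PseudobulkProfile,
    profile_b: PseudobulkProfile,
    orthology: OrthologyMap,
    cell_type_subset: Sequence[str] | None = None,
    group: str | None = None,
    log_transform: bool = False,
) -> ExpressologTable:
    """Bidirectional rank-standardized expression-profile similarity of
    1:1 orthologues across the shared consensus cell types.

    Genes with zero variance over the (sub)group of cell types have
    undefined correlations; those entries take the median rank (a count of
    affected genes is logged).
    """
    a, b, genes_a, genes_b, _ = _aligned_matrices(profile_a, profile_b, orthology, cell_type_subset)
    if log_transform:
        a, b = np.log1p(a), np.log1p(b)
    za, dega = _row_standardize(a)
    zb, degb = _row_standardize(b)
    n_deg = int(dega.sum() + degb.sum())
    if n_deg:
        log.info("%d constant profiles assigned the median rank", n_deg)
    corr = za @ zb.T
    corr[dega, :] = np.nan
    corr[:, degb] = np.nan
    n = corr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 genes to rank")
    diag = np.arange(n)
    score_ab = (rank_rows(corr)[diag, diag] - 1.0) / (n - 1.0)
    score_ba = (rank_cols(corr)[diag, diag] - 1.0) / (n - 1.0)
    table = pd.DataFrame(
        {
            "gene_b": genes_b,
            "score_ab": score_ab,
            "score_ba": score_ba,
            "score": (score_ab + score_ba) / 2.0,
        },
        index=pd.Index(genes_a, name="gene_a"),
    )
    return ExpressologTable(table, profile_a.species, profile_b.species, n, group)


def expressolog_scores_by_group(
    profile_a: PseudobulkProfile,
    profile_b: PseudobulkProfile,
    orthology: OrthologyMap,
    groups: Mapping[str, Sequence[str]],
    log_transform: bool = False,
) -> dict[str, ExpressologTable]:
    """Expressolog scores recomputed over each named cell-type group
    (class, subclass or meta-cluster), ranking within the full gene
    universe but correlating only over the group's cell types."""
    out = {}
    for name, cell_types in groups.items():
        out[name] = expressolog_scores(
            profile_a, profile_b, orthology,
            cell_type_subset=cell_types, group=name, log_transform=log_transform,
        )
    return out


def isoform_self_prediction(
    profile_a: PseudobulkProfile,
    profile_b: PseudobulkProfile,
    gene_of: pd.Series,
    min_cells: int = 10,
    min_total_expression: float = 5.0,
) -> float:
    """Mean AUROC for isoforms predicting themselves among sibling isoforms.

    Filters mirror the isoform workflow: cell types backed by at least
    ``min_cells`` nuclei in both species, isoforms with total expression of
    at least ``min_total_expression`` (TPM-scale) in both species, and
    genes with at least two isoforms shared by both species.  Per gene,
    cross-species expressolog scores are computed for all isoform pairs and
    each isoform's self-score is ranked among its siblings.
    """
    shared = profile_a.cell_types.intersection(profile_b.cell_types)
    for prof in (profile_a, profile_b):
        if prof.n_cells is not None:
            ok = prof.n_cells[prof.n_cells >= min_cells].index
            shared = shared.intersection(ok)
    if len(shared) < 3:
        raise ValueError("fewer than 3 cell types pass the cell-count filter")
    shared = shared.sort_values()

    isoforms = profile_a.gene_ids.intersection(profile_b.gene_ids)
    a = profile_a.matrix.loc[isoforms, shared]
    b = profile_b.matrix.loc[isoforms, shared]
    expressed = (a.sum(axis=1) >= min_total_expression) & (b.sum(axis=1) >= min_total_expression)
    isoforms = isoforms[expressed.to_numpy()]
    genes = gene_of.reindex(isoforms)
    sizes = genes.groupby(genes).transform("size")
    isoforms = isoforms[(sizes >= 2).to_numpy()]
    if len(isoforms) == 0:
        raise ValueError("no gene passes the isoform filters")
    genes = gene_of.reindex(isoforms)

    za, dega = _row_standardize(a.loc[isoforms].to_numpy(dtype=float))
    zb, degb = _row_standardize(b.loc[isoforms].to_numpy(dtype=float))
    corr = za @ zb.T
    corr[dega, :] = np.nan
    corr[:, degb] = np.nan
    n = corr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 isoforms")
    s_ab = (rank_rows(corr) - 1.0) / (n - 1.0)
    s_ba = (rank_cols(corr) - 1.0) / (n - 1.0)
    s = (s_ab + s_ba) / 2.0

    from scipy.stats import rankdata

    aurocs = []
    pos = pd.Series(np.arange(n), index=isoforms)
    for _, sibs in genes.groupby(genes).groups.items():
        idx = pos.loc[list(sibs)].to_numpy()
        for i in idx:
            sib_scores = s[i, idx]
            r = rankdata(sib_scores)[np.flatnonzero(idx == i)[0]]
            aurocs.append(auroc_from_rank(r, len(idx)))
    return float(np.mean(aurocs))
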