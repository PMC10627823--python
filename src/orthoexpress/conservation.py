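"""Cross-species conservation of co-expression neighbourhoods.

For a gene pairing (i in species A, j in species B): take i's top-k
co-expression partners in A's network, map them through the 1:1 orthology,
and compute the AUROC of the mapped partners in the ranking of all genes
by co-expression with j in B's network; average the two directions.  The
'co-expression conservation' of an orthologue is the specificity of this
raw AUROC — its ascending rank among all N candidate pairings for that
gene, converted to [0, 1] and bidirectionally averaged.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from ._rank import mann_whitney_auroc
from .datasets import OrthologyMap
from .networks import CoexpressionNetwork

__all__ = ["ConservationTable", "neighbourhood_auroc", "conservation_scores", "align_networks"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ConservationTable:
    """Per-gene raw neighbourhood AUROC and conservation (specificity)."""

    table: pd.DataFrame  # index gene (species A namespace); raw_auroc, conservation
    species_a: str
    species_b: str
    k: int

    def __post_init__(self) -> None:
        for col in ("raw_auroc", "conservation"):
            v = self.table[col]
            if ((v < -1e-9) | (v > 1 + 1e-9)).any():
                raise ValueError(f"{col} must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "pair", f"{self.species_a}|{self.species_b}")
        out.to_csv(path, sep="\t")


def align_networks(
    net_a: CoexpressionNetwork, net_b: CoexpressionNetwork, orthology: OrthologyMap
) -> tuple[CoexpressionNetwork, CoexpressionNetwork, pd.Index, pd.Series]:
    """Restrict both networks to shared 1:1 orthologues, B renamed into A's
    gene namespace and both ordered identically; also returns the A->B
    gene map used."""
    sa = net_a.species or "a"
    sb = net_b.species or "b"
    try:
        amap = orthology.pair_map(sa, sb)
    except KeyError:
        shared = net_a.gene_ids.intersection(net_b.gene_ids)
        if len(shared) == 0:
            raise
        # identity mapping: the networks already share gene identifiers
        log.info("pair (%s, %s) not in orthology; matching %d shared gene ids", sa, sb, len(shared))
        amap = pd.Series(shared.to_numpy(), index=shared)
    genes_a = net_a.gene_ids.intersection(amap.index)
    genes_a = genes_a[pd.Index(amap.loc[genes_a]).isin(net_b.gene_ids)].sort_values()
    if len(genes_a) < 3:
        raise ValueError("fewer than 3 shared orthologues between the networks")
    genes_b = pd.Index(amap.loc[genes_a])
    a = net_a.subset(genes_a)
    b = net_b.subset(genes_b)
    b.gene_ids = pd.Index(genes_a)  # rename into A's namespace
    return a, b, pd.Index(genes_a), amap


def _top_partners(row: np.ndarray, self_idx: int, k: int) -> np.ndarray:
    """Indices of the top-k co-expression partners of one gene, self
    excluded; ties at the k-th weight are all included."""
    w = row.copy()
    w[self_idx] = -np.inf
    if k >= len(w) - 1:
        return np.flatnonzero(np.isfinite(w))
    kth = np.partition(w, len(w) - k)[len(w) - k]
    partners = np.flatnonzero(w >= kth)
    if len(partners) > k:
        log.info("tie at the k-th partner: neighbourhood of size %d used", len(partners))
    return partners


def neighbourhood_auroc(
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    orthology: OrthologyMap,
    gene_pair: tuple[str, str],
    k: int = 10,
) -> float:
    """Bidirectional top-k neighbourhood AUROC for one gene pairing.

    ``gene_pair`` is (gene in A's namespace, gene in B's namespace); the
    self-edge is excluded from both the partner set and the ranking
    population.
    """
    a, b, genes, amap = align_networks(net_a, net_b, orthology)
    gi, gj_b = gene_pair
    if gi not in genes:
        raise KeyError(f"gene {gi!r} absent after orthology restriction")
    # translate j into A's namespace
    inv = pd.Series(amap.index.to_numpy(), index=pd.Index(amap.to_numpy()))
    if gj_b in inv.index:
        gj = inv.loc[gj_b]
    elif gj_b in genes:
        gj = gj_b
    else:
        raise KeyError(f"gene {gj_b!r} absent after orthology restriction")
    i = genes.get_loc(gi)
    j = genes.get_loc(gj)

    def one_direction(src: np.ndarray, dst: np.ndarray, i: int, j: int) -> float:
        partners = _top_partners(src[i], i, k)
        partners = partners[partners != j]
        scores = dst[:, j]
        mask = np.ones(len(scores), dtype=bool)
        mask[j] = False
        is_pos = np.zeros(len(scores), dtype=bool)
        is_pos[partners] = True
        return mann_whitney_auroc(scores[mask & is_pos], scores[mask & ~is_pos])

    fwd = one_direction(a.matrix, b.matrix, i, j)
    rev = one_direction(b.matrix, a.matrix, j, i)
    return float((fwd + rev) / 2.0)


def _direction_auroc_matrix(src: np.ndarray, dst: np.ndarray, k: int) -> np.ndarray:
    """AUROC[i, j] of src-gene i's top-k partner set within dst-column j's
    co-expression ranking, for all pairings, self-edges excluded.

    Realized as a (sparse top-k indicator) x (column-ranked network)
    product; identical to the per-pair definition.
    """
    n = src.shape[0]
    rows, cols = [], []
    for i in range(n):
        partners = _top_partners(src[i], i, k)
        rows.extend([i] * len(partners))
        cols.extend(partners)
    p = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))

    d = dst.copy().astype(float)
    np.fill_diagonal(d, -np.inf)
    colranks = rankdata(d, axis=0) - 1.0  # rank within the n-1 non-self genes
    np.fill_diagonal(colranks, 0.0)

    s = np.asarray(p @ colranks)  # sum of partner ranks per (i, j)
    p_dense_col = np.asarray(p.todense())
    n_pos = np.asarray(p.sum(axis=1)).ravel()[:, None] - p_dense_col  # j removed if partner
    n_neg = (n - 1) - n_pos
    with np.errstate(invalid="ignore", divide="ignore"):
        auroc = (s - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return auroc


def conservation_scores(
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    orthology: OrthologyMap,
    k: int = 10,
) -> ConservationTable:
    """Raw neighbourhood AUROC and conservation for every orthologue.

    The AUROC is computed for all N x N gene pairings; conservation is the
    ascending rank of the orthologue's AUROC among all pairings of that
    gene (per direction, then averaged), scaled to [0, 1].
    """
    a, b, genes, _ = align_networks(net_a, net_b, orthology)
    n = len(genes)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the gene count {n}")
    ab = _direction_auroc_matrix(a.matrix, b.matrix, k)
    ba = _direction_auroc_matrix(b.matrix, a.matrix, k)
    diag = np.arange(n)
    raw = (ab[diag, diag] + ba[diag, diag]) / 2.0

    def diag_rank_rows(m: np.ndarray) -> np.ndarray:
        d = m[diag, diag][:, None]
        less = (m < d).sum(axis=1)
        equal = (m == d).sum(axis=1)
        r = less + (equal + 1) / 2.0
        return (r - 1.0) / (n - 1.0)

    specificity = (diag_rank_rows(ab) + diag_rank_rows(ba)) / 2.0
    table = pd.DataFrame(
        {"raw_auroc": raw, "conservation": specificity}, index=pd.Index(genes, name="gene")
    )
    return ConservationTable(table, net_a.species or "a", net_b.species or "b", k)
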