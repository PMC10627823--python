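"""Cross-dataset cell-type replicability by neighbor voting.

Each cell is rank-standardized over a shared set of highly variable genes;
a test cell's vote for a training cell type is its mean Spearman
similarity to that type's cells (the closed-form "fast" variant of
neighbor voting).  Replicability of a candidate test cell type is the
AUROC of its member cells' votes against a comparison population:

* ``one_vs_all`` — all other cells of the test dataset;
* ``one_vs_best`` — only the cells of the second-closest test cell type,
  a stricter specificity measure reported for the two closest neighbours
  of each training type.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._rank import mann_whitney_auroc
from .datasets import CellPopulationDataset, OrthologyMap, shared_orthologue_universe

__all__ = [
    "ReplicabilityMatrix",
    "select_variable_genes",
    "replicability",
    "permutation_threshold_check",
    "gene_set_replicability",
]

log = logging.getLogger(__name__)

LEVEL_COLUMNS = {"class": "class_label", "subclass": "subclass", "cluster": "cluster"}


@dataclasses.dataclass
class ReplicabilityMatrix:
    """Train x test cell-type AUROC matrix.

    Rows and columns are node identifiers ``"dataset|label"``; entries are
    NaN where the pair was not scored (same dataset, or outside the two
    closest neighbours in ``one_vs_best`` mode).  ``node_meta`` maps each
    node to its dataset, species and label.
    """

    scores: pd.DataFrame
    mode: str
    hvg_set: pd.Index
    node_meta: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("AUROC scores must lie in [0, 1]")

    def datasets(self) -> list[str]:
        return sorted(self.node_meta["dataset"].unique())

    def best_hits(self) -> pd.DataFrame:
        """Per (train node, test dataset): the top-voted test node and score."""
        rows = []
        meta = self.node_meta.set_index("node")
        for train in self.scores.index:
            s = self.scores.loc[train].dropna()
            if s.empty:
                continue
            by_ds = s.groupby(meta.loc[s.index, "dataset"].to_numpy())
            for ds_name, grp in by_ds:
                grp = grp.sort_index()  # lexicographic tie-break, deterministic
                best = grp.idxmax()
                rows.append({"train": train, "test_dataset": ds_name, "best": best,
                             "score": float(grp.loc[best])})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.index.name = f"mode={self.mode}"
        out.to_csv(path, sep="\t")


def _detect_level(level: str) -> str:
    if level not in LEVEL_COLUMNS:
        raise ValueError(f"level must be one of {sorted(LEVEL_COLUMNS)}, got {level!r}")
    return LEVEL_COLUMNS[level]


def select_variable_genes(
    datasets: Sequence[CellPopulationDataset],
    orthology: OrthologyMap | None,
    n_genes: int,
    n_bins: int = 10,
) -> pd.Index:
    """Highly variable genes detected in every dataset.

    Within each dataset, genes are binned by mean CPM into ``n_bins``
    equal-occupancy strata and ranked by variance within their bin (high
    variance = good rank).  Genes must be detected (non-constant) in every
    dataset; the cross-dataset criterion is the median within-bin variance
    rank, and the top ``n_genes`` by that criterion are returned, ties
    broken by gene identifier.
    """
    if orthology is not None and len(datasets) > 1:
        datasets = shared_orthologue_universe(datasets, orthology)
    universe = datasets[0].gene_ids
    for ds in datasets[1:]:
        if not universe.equals(ds.gene_ids):
            universe = universe.intersection(ds.gene_ids)
    if len(universe) == 0:
        raise ValueError("datasets share no genes")
    per_ds_rank = []
    detected = np.ones(len(universe), dtype=bool)
    for ds in datasets:
        sub = ds.subset_genes(universe)
        x = sub.cpm()
        mean = x.mean(axis=1)
        var = x.var(axis=1)
        # a gene constant in raw counts (or in CPM) is not variable here
        detected &= (var > 0) & (sub.dense_counts().var(axis=1) > 0)
        bin_rank = rankdata(mean, method="average")
        bins = np.floor((bin_rank - 1) / len(mean) * n_bins).astype(int)
        score = np.empty(len(mean))
        for b in np.unique(bins):
            m = bins == b
            # fraction of the bin a gene's variance exceeds
            score[m] = rankdata(var[m]) / m.sum()
        per_ds_rank.append(score)
    criterion = np.median(per_ds_rank, axis=0)
    order = pd.DataFrame({"gene": universe, "crit": criterion, "det": detected})
    order = order[order["det"]]
    if order.empty:
        raise ValueError("no gene is variable in every dataset")
    order = order.sort_values(["crit", "gene"], ascending=[False, True], kind="stable")
    return pd.Index(order["gene"].head(n_genes))


def _rank_cells(ds: CellPopulationDataset, hvg: pd.Index) -> np.ndarray:
    """Per-cell rank-standardized expression over hvg genes, each cell
    centered and scaled to unit norm (so dot products are Spearman)."""
    x = ds.subset_genes(hvg).dense_counts()
    r = rankdata(x, axis=0)
    r -= r.mean(axis=0, keepdims=True)
    norms = np.sqrt((r**2).sum(axis=0))
    norms[norms == 0] = 1.0
    return r / norms


def replicability(
    datasets: Sequence[CellPopulationDataset],
    level: str = "cluster",
    mode: str = "one_vs_all",
    hvg: pd.Index | Sequence[str] | None = None,
    orthology: OrthologyMap | None = None,
    n_hvg: int = 500,
) -> ReplicabilityMatrix:
    """Neighbor-voting AUROCs for every ordered cross-dataset pair.

    When ``hvg`` is None, highly variable genes are selected from the
    datasets themselves (``n_hvg`` of them).
    """
    if mode not in ("one_vs_all", "one_vs_best"):
        raise ValueError(f"mode must be one_vs_all or one_vs_best, got {mode!r}")
    if len(datasets) < 2:
        raise ValueError("replicability needs at least two datasets")
    col = _detect_level(level)
    if hvg is None:
        hvg = select_variable_genes(datasets, orthology, n_hvg)
    hvg = pd.Index(hvg)
    if orthology is not None:
        datasets = shared_orthologue_universe(datasets, orthology)
        hvg = hvg.intersection(datasets[0].gene_ids)

    names = []
    for i, ds in enumerate(datasets):
        names.append(ds.name if ds.name not in names else f"{ds.name}#{i}")
    ranked = [_rank_cells(ds, hvg) for ds in datasets]
    labels = [ds.cell_meta[col].astype(str).to_numpy() for ds in datasets]

    node_rows, nodes_by_ds = [], []
    for nm, ds, lab in zip(names, datasets, labels):
        uniq = sorted(pd.unique(lab))
        nodes_by_ds.append([f"{nm}|{u}" for u in uniq])
        for u in uniq:
            node_rows.append({"node": f"{nm}|{u}", "dataset": nm,
                              "species": ds.species, "label": u})
    node_meta = pd.DataFrame(node_rows)
    all_nodes = node_meta["node"].tolist()
    scores = pd.DataFrame(np.nan, index=all_nodes, columns=all_nodes)

    for i_tr, (nm_tr, r_tr, lab_tr) in enumerate(zip(names, ranked, labels)):
        types_tr = sorted(pd.unique(lab_tr))
        small_tr = {t for t in types_tr if (lab_tr == t).sum() < 2}
        for t in small_tr:
            log.warning("train type %s|%s has <2 cells; scores reported missing", nm_tr, t)
        # genes x train-type mean profiles
        centroids = np.column_stack(
            [r_tr[:, lab_tr == t].mean(axis=1) for t in types_tr]
        )
        for i_te, (nm_te, r_te, lab_te) in enumerate(zip(names, ranked, labels)):
            if i_te == i_tr:
                continue
            votes = r_te.T @ centroids  # test cells x train types
            types_te = sorted(pd.unique(lab_te))
            members = {t: lab_te == t for t in types_te}
            small_te = {t for t in types_te if members[t].sum() < 2}
            for t in small_te:
                log.warning("test type %s|%s has <2 cells; scores reported missing", nm_te, t)
            for j, t_tr in enumerate(types_tr):
                if t_tr in small_tr:
                    continue
                v = votes[:, j]
                row = f"{nm_tr}|{t_tr}"
                if mode == "one_vs_all":
                    rv = rankdata(v)
                    for t_te in types_te:
                        if t_te in small_te:
                            continue
                        m = members[t_te]
                        n_pos = int(m.sum())
                        n_neg = len(v) - n_pos
                        u = rv[m].sum() - n_pos * (n_pos + 1) / 2.0
                        scores.loc[row, f"{nm_te}|{t_te}"] = u / (n_pos * n_neg)
                else:
                    mean_votes = pd.Series(
                        {t: v[members[t]].mean() for t in types_te if t not in small_te}
                    ).sort_index()
                    if len(mean_votes) < 2:
                        continue
                    ranked_types = mean_votes.sort_values(ascending=False, kind="stable")
                    best, second = ranked_types.index[0], ranked_types.index[1]
                    if np.isclose(ranked_types.iloc[0], ranked_types.iloc[1]):
                        log.info("tie for closest neighbour of %s in %s; lexicographic break", row, nm_te)
                    a = mann_whitney_auroc(v[members[best]], v[members[second]])
                    scores.loc[row, f"{nm_te}|{best}"] = a
                    scores.loc[row, f"{nm_te}|{second}"] = 1.0 - a
    return ReplicabilityMatrix(scores, mode, hvg, node_meta)


def permutation_threshold_check(
    datasets: Sequence[CellPopulationDataset],
    n_perms: int = 10,
    threshold: float = 0.6,
    level: str = "cluster",
    hvg: pd.Index | None = None,
    orthology: OrthologyMap | None = None,
    seed: int = 0,
) -> int:
    """Total cross-dataset one_vs_best hits above ``threshold`` after
    shuffling within-dataset cluster labels, summed over permutations.

    With well-populated clusters the permuted labels carry no signal, so
    best-vs-second AUROCs concentrate near 0.5 and a threshold of 0.6
    yields no hits.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    col = _detect_level(level)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perms):
        shuffled = []
        for ds in datasets:
            meta = ds.cell_meta.copy()
            meta[col] = rng.permutation(meta[col].to_numpy())
            shuffled.append(CellPopulationDataset(ds.counts, ds.gene_ids, meta, ds.name))
        rep = replicability(shuffled, level=level, mode="one_vs_best",
                            hvg=hvg, orthology=orthology)
        vals = rep.scores.to_numpy(dtype=float)
        hits += int(np.nansum(vals > threshold))
    return hits


def gene_set_replicability(
    datasets: Sequence[CellPopulationDataset],
    gene_sets: Mapping[str, Sequence[str]],
    level: str = "subclass",
    orthology: OrthologyMap | None = None,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Cell-type classification performance of each curated gene set.

    Replicability (one_vs_all) is recomputed restricted to each set's
    genes; the returned frame holds, per set, the mean AUROC of matched
    cell types for same-species dataset pairs (``within``) and
    cross-species pairs (``cross``).  Sets with fewer than ``min_genes``
    mapped genes are skipped with a warning.
    """
    if orthology is not None:
        datasets = shared_orthologue_universe(datasets, orthology)
    universe = datasets[0].gene_ids
    for ds in datasets[1:]:
        universe = universe.intersection(ds.gene_ids)
    rows = []
    for name, genes in gene_sets.items():
        present = pd.Index(genes).intersection(universe)
        if len(present) < min_genes:
            log.warning("gene set %r skipped: only %d mapped genes", name, len(present))
            continue
        rep = replicability(datasets, level=level, mode="one_vs_all", hvg=present)
        meta = rep.node_meta.set_index("node")
        within, cross = [], []
        for tr in rep.scores.index:
            for te in rep.scores.columns:
                val = rep.scores.loc[tr, te]
                if not np.isfinite(val) or meta.loc[tr, "label"] != meta.loc[te, "label"]:
                    continue
                bucket = within if meta.loc[tr, "species"] == meta.loc[te, "species"] else cross
                bucket.append(val)
        rows.append(
            {
                "gene_set": name,
                "n_genes": len(present),
                "within_auroc": float(np.mean(within)) if within else np.nan,
                "cross_auroc": float(np.mean(cross)) if cross else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("gene_set")
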