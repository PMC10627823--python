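"""Consensus cross-species cell types from replicability scores.

Within-species clusters become nodes of an undirected graph; an edge joins
two clusters of different species when they are reciprocal best hits or
when either directional one_vs_best AUROC exceeds a threshold.  Connected
components touching at least two species are the cross-species clusters;
left-over clusters are ambiguous and can be rescued by a majority vote
over their closest one_vs_all neighbours.
"""
from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .voting import ReplicabilityMatrix

__all__ = [
    "ConsensusTaxonomy",
    "build_consensus",
    "assign_ambiguous",
    "shared_consensus",
    "taxonomy_robustness",
    "taxonomy_from_truth",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ConsensusTaxonomy:
    """Mapping of (species, cluster) nodes to consensus cluster ids.

    ``assignment`` is indexed by node id ``"dataset|cluster"``; unassigned
    (ambiguous) nodes hold NA.  ``levels`` optionally carries per-consensus
    class/subclass/meta-cluster labels.
    """

    assignment: pd.Series
    node_meta: pd.DataFrame
    levels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.assignment = self.assignment.astype("object")

    @property
    def consensus_ids(self) -> list[str]:
        return sorted(self.assignment.dropna().unique())

    @property
    def species_of_node(self) -> pd.Series:
        return self.node_meta.set_index("node")["species"]

    def members(self, consensus_id: str) -> list[str]:
        return list(self.assignment[self.assignment == consensus_id].index)

    def ambiguous_nodes(self) -> list[str]:
        return list(self.assignment[self.assignment.isna()].index)

    def to_frame(self) -> pd.DataFrame:
        out = self.node_meta.set_index("node").copy()
        out["consensus_id"] = self.assignment
        return out.reset_index()

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignment": {k: (None if pd.isna(v) else v) for k, v in self.assignment.items()},
            "levels": None if self.levels is None else self.levels.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _check_pairs(rep: ReplicabilityMatrix) -> None:
    meta = rep.node_meta.set_index("node")
    datasets = sorted(meta["dataset"].unique())
    for a, b in itertools.combinations(datasets, 2):
        rows = meta.index[meta["dataset"] == a]
        cols = meta.index[meta["dataset"] == b]
        block = rep.scores.loc[rows, cols].to_numpy(dtype=float)
        if not np.isfinite(block).any():
            raise ValueError(f"replicability matrix missing the dataset pair ({a}, {b})")


def build_consensus(rep: ReplicabilityMatrix, auroc_threshold: float = 0.6) -> ConsensusTaxonomy:
    """Cross-species clusters from a one_vs_best replicability matrix.

    An edge joins (train, test) clusters of different datasets when they
    are mutual best hits or when either directional AUROC exceeds
    ``auroc_threshold``.  Components containing at least two species are
    kept as consensus clusters; the rest are ambiguous.
    """
    if rep.mode != "one_vs_best":
        raise ValueError("build_consensus expects a one_vs_best replicability matrix")
    _check_pairs(rep)
    meta = rep.node_meta.set_index("node")
    g = nx.Graph()
    g.add_nodes_from(meta.index)

    hits = rep.best_hits()
    best_of = {(r["train"], r["test_dataset"]): r["best"] for _, r in hits.iterrows()}
    for (train, _), best in best_of.items():
        ds_train = meta.loc[train, "dataset"]
        if best_of.get((best, ds_train)) == train:
            g.add_edge(train, best)
    vals = rep.scores.to_numpy(dtype=float)
    rr, cc = np.where(np.isfinite(vals) & (vals > auroc_threshold))
    for i, j in zip(rr, cc):
        u, v = rep.scores.index[i], rep.scores.columns[j]
        if meta.loc[u, "dataset"] != meta.loc[v, "dataset"]:
            g.add_edge(u, v)

    assignment = pd.Series(pd.NA, index=meta.index, dtype="object")
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    k = 0
    for comp in comps:
        species = {meta.loc[n, "species"] for n in comp}
        if len(species) >= 2:
            cid = f"CS{k:03d}"
            k += 1
            for n in comp:
                assignment.loc[n] = cid
    taxonomy = ConsensusTaxonomy(assignment, rep.node_meta.copy())
    log.info("%d consensus clusters; %d ambiguous clusters", k, assignment.isna().sum())
    return taxonomy


def assign_ambiguous(
    taxonomy: ConsensusTaxonomy,
    rep_all: ReplicabilityMatrix,
    k1: int = 10,
    k2: int = 20,
) -> ConsensusTaxonomy:
    """Rescue ambiguous clusters by a strict majority of their closest
    neighbours under one_vs_all replicability.

    A cluster joins the consensus cluster holding more than half of its
    top ``k1`` neighbours; failing that, the vote is repeated with the top
    ``k2``, still requiring a strict majority; failing again, the cluster
    stays unassigned.  Neighbour similarity is the mean of the two
    directional one_vs_all scores; ties break lexicographically.
    """
    if rep_all.mode != "one_vs_all":
        raise ValueError("assign_ambiguous expects a one_vs_all replicability matrix")
    meta = rep_all.node_meta.set_index("node")
    assignment = taxonomy.assignment.copy()
    sym = (rep_all.scores.add(rep_all.scores.T)) / 2.0
    sym = sym.combine_first(rep_all.scores).combine_first(rep_all.scores.T)

    for node in taxonomy.ambiguous_nodes():
        if node not in sym.index:
            continue
        sims = sym.loc[node].drop(labels=[node], errors="ignore").dropna()
        same_ds = meta.loc[sims.index, "dataset"] == meta.loc[node, "dataset"]
        sims = sims[~same_ds.to_numpy()]
        if sims.empty:
            continue
        sims = sims.sort_index().sort_values(ascending=False, kind="stable")
        for k in (k1, k2):
            top = sims.head(k)
            votes = assignment.reindex(top.index).dropna()
            if votes.empty:
                continue
            counts = votes.value_counts()
            if counts.iloc[0] * 2 > k:
                winners = counts[counts == counts.iloc[0]].index.sort_values()
                assignment.loc[node] = winners[0]
                break
    return ConsensusTaxonomy(assignment, taxonomy.node_meta.copy(), taxonomy.levels)


def shared_consensus(taxonomy: ConsensusTaxonomy, n_species: int | None = None) -> list[str]:
    """Consensus cluster ids containing at least one cluster from every species."""
    species_of = taxonomy.species_of_node
    if n_species is None:
        n_species = species_of.nunique()
    shared = []
    for cid in taxonomy.consensus_ids:
        members = taxonomy.members(cid)
        if species_of.loc[members].nunique() >= n_species:
            shared.append(cid)
    return shared


def taxonomy_from_truth(truth) -> ConsensusTaxonomy:
    """The ideal taxonomy implied by a simulation's planted cluster homology.

    Useful to isolate downstream stages (pseudobulk, screen) from the
    consensus-construction stage in benchmarks.
    """
    nodes, cids, species = [], [], []
    for (sp_name, cluster), t in sorted(truth.true_cluster_homology.items()):
        nodes.append(f"{sp_name}|{cluster}")
        cids.append(f"CS{int(t):03d}")
        species.append(sp_name)
    assignment = pd.Series(cids, index=pd.Index(nodes), dtype="object")
    meta = pd.DataFrame(
        {
            "node": nodes,
            "dataset": species,
            "species": species,
            "label": [n.split("|", 1)[1] for n in nodes],
        }
    )
    return ConsensusTaxonomy(assignment, meta)


def taxonomy_robustness(a: ConsensusTaxonomy, b: ConsensusTaxonomy) -> float:
    """Adjusted Rand index between two taxonomies over the same cluster universe."""
    if not a.assignment.index.sort_values().equals(b.assignment.index.sort_values()):
        raise ValueError("taxonomies cover different (species, cluster) universes")
    both = a.assignment.notna() & b.assignment.reindex(a.assignment.index).notna()
    idx = a.assignment.index[both]
    if len(idx) == 0:
        return float("nan")
    la = pd.factorize(a.assignment.loc[idx])[0]
    lb = pd.factorize(b.assignment.loc[idx])[0]
    return float(adjusted_rand_score(la, lb))
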