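"""Screen for genes with lineage-specific concordant divergence.

The decision procedure: (1) drop lowly expressed genes (bottom percentile
of cross-species mean pseudobulk expression); (2) flag genes whose
class-level expressolog score against another species in the focal
lineage's comparisons falls below a threshold (expression-divergent); (3)
among those, test per gene whether co-expression conservation between the
focal species and other species is lower than between pairs of other
species (one-sided Wilcoxon rank-sum, Benjamini-Hochberg adjusted).  Genes
passing both filters are called focal-lineage-divergent.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .conservation import ConservationTable, conservation_scores
from .datasets import OrthologyMap
from .expressolog import ExpressologTable, PseudobulkProfile, expressolog_scores
from .networks import CoexpressionNetwork

__all__ = [
    "ScreenConfig",
    "DivergenceReport",
    "expression_filter",
    "class_divergence",
    "conservation_test",
    "run_screen",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the divergence screen (defaults follow the workflow)."""

    focal_species: str = "human"
    expression_percentile: float = 10.0
    expressolog_threshold: float = 0.55
    k: int = 10
    alpha: float = 0.05
    pair_rule: str = "any"  # flag when < threshold in any focal-vs-other pair ('all': every pair)
    exact_max_group: int = 25  # exact Wilcoxon up to this group size


@dataclasses.dataclass
class DivergenceReport:
    """Per-gene evidence trail and final calls of the screen."""

    table: pd.DataFrame
    config: ScreenConfig
    summary: dict

    def calls(self, category: str = "focal-lineage-divergent") -> pd.Index:
        return self.table.index[self.table["call"] == category]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")

    def to_json(self, path: str | Path) -> None:
        payload = {"config": dataclasses.asdict(self.config), "summary": self.summary}
        Path(path).write_text(json.dumps(payload, indent=1))


def expression_filter(
    profiles: Sequence[PseudobulkProfile] | Mapping[str, PseudobulkProfile],
    percentile: float = 10.0,
    orthology: OrthologyMap | None = None,
) -> pd.Index:
    """Genes above the bottom expression percentile.

    The per-gene statistic is the mean pseudobulk expression over all cell
    types and species; genes below the requested percentile of that
    distribution are removed.  Profiles must share the gene namespace
    (orthology with shared identifiers) or be mappable via ``orthology``.
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    universe = profiles[0].gene_ids
    for p in profiles[1:]:
        genes = p.gene_ids
        if orthology is not None and not genes.equals(universe):
            amap = orthology.pair_map(profiles[0].species, p.species)
            genes = pd.Index(amap.index)[pd.Index(amap).isin(p.gene_ids)]
        universe = universe.intersection(genes)
    means = []
    for p in profiles:
        m = p.matrix
        if not universe.isin(m.index).all() and orthology is not None:
            amap = orthology.pair_map(profiles[0].species, p.species)
            m = m.loc[amap.loc[universe]]
            m.index = universe
        means.append(m.loc[universe].mean(axis=1))
    overall = pd.concat(means, axis=1).mean(axis=1)
    # bottom-percentile by count: the floor(n * p / 100) lowest-mean genes
    # are removed (deterministic ties: sort by value then gene id)
    n_remove = int(np.floor(len(overall) * percentile / 100.0))
    order = overall.to_frame("mean").sort_values(["mean"], kind="stable").index
    removed = set(order[:n_remove])
    return universe[[g not in removed for g in universe]]


def class_divergence(
    class_tables: Mapping[str, Mapping[str, ExpressologTable]],
    threshold: float = 0.55,
    rule: str = "any",
) -> tuple[pd.Index, pd.DataFrame]:
    """Genes with a low class-level expressolog score in the focal
    comparisons.

    ``class_tables`` maps other-species name -> {class name -> table of
    focal-vs-other scores}.  A gene is flagged when its score drops below
    ``threshold`` in at least one class — in at least one species pair
    under ``rule='any'`` (default), or in every pair under ``rule='all'``.
    Returns the flagged genes and a frame recording which classes diverge.
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    per_class: dict[str, pd.DataFrame] = {}
    for other, tables in class_tables.items():
        for cls, tab in tables.items():
            per_class.setdefault(cls, pd.DataFrame())[other] = tab.scores
    records = {}
    for cls, frame in per_class.items():
        low = frame < threshold
        hit = low.any(axis=1) if rule == "any" else low.all(axis=1)
        records[cls] = hit
    hits = pd.DataFrame(records)
    flagged = hits.index[hits.any(axis=1)]
    classes = hits.apply(lambda row: ",".join(sorted(hits.columns[row])), axis=1)
    detail = pd.DataFrame({"divergent_classes": classes, "n_divergent_classes": hits.sum(axis=1)})
    return flagged, detail


def conservation_test(
    tables: Mapping[tuple[str, str], ConservationTable],
    focal: str,
    alpha: float = 0.05,
    genes: Sequence[str] | None = None,
    exact_max_group: int = 25,
) -> pd.DataFrame:
    """One-sided Wilcoxon rank-sum per gene: is co-expression conservation
    lower in focal-vs-other pairs than in other-vs-other pairs?

    ``tables`` maps (species_a, species_b) -> ConservationTable with genes
    in a shared namespace.  P values are Benjamini-Hochberg adjusted across
    genes; exact null distribution for group sizes up to
    ``exact_max_group``, normal approximation with continuity correction
    above.
    """
    focal_cols, bg_cols = {}, {}
    for (sa, sb), tab in tables.items():
        series = tab.table["conservation"]
        key = f"{sa}|{sb}"
        (focal_cols if focal in (sa, sb) else bg_cols)[key] = series
    if not bg_cols:
        raise ValueError("background group empty: need conservation for non-focal species pairs")
    if not focal_cols:
        raise ValueError(f"no conservation tables involve the focal species {focal!r}")
    fg = pd.DataFrame(focal_cols)
    bg = pd.DataFrame(bg_cols)
    idx = fg.index.intersection(bg.index)
    if genes is not None:
        idx = idx.intersection(pd.Index(genes))
    fg, bg = fg.loc[idx], bg.loc[idx]

    pvals = np.ones(len(idx))
    for i in range(len(idx)):
        x = fg.iloc[i].dropna().to_numpy()
        y = bg.iloc[i].dropna().to_numpy()
        if x.size == 0 or y.size == 0:
            pvals[i] = np.nan
            continue
        method = "exact" if max(x.size, y.size) <= exact_max_group else "asymptotic"
        pvals[i] = mannwhitneyu(x, y, alternative="less", method=method).pvalue
    ok = np.isfinite(pvals)
    adj = np.full_like(pvals, np.nan)
    if ok.any():
        adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "mean_focal_conservation": fg.mean(axis=1),
            "mean_background_conservation": bg.mean(axis=1),
            "p": pvals,
            "p_adj": adj,
            "significant": adj < alpha,
        },
        index=idx,
    )


def run_screen(
    profiles: Mapping[str, PseudobulkProfile],
    networks: Sequence[CoexpressionNetwork],
    orthology: OrthologyMap,
    class_of_cell_type: Mapping[str, str] | pd.Series,
    config: ScreenConfig = ScreenConfig(),
) -> DivergenceReport:
    """Full decision procedure composing the three stages.

    ``profiles`` maps primate species -> pseudobulk profile over consensus
    cell types (focal species included); ``networks`` are aggregate
    co-expression networks for the focal species plus the multi-species
    background.  ``class_of_cell_type`` assigns each consensus cell type to
    a cell class for the class-level expressolog scores.
    """
    focal = config.focal_species
    if focal not in profiles:
        raise KeyError(f"focal species {focal!r} missing from profiles")
    class_of = pd.Series(class_of_cell_type)
    retained = expression_filter(list(profiles.values()), config.expression_percentile, orthology)
    log.info("expression filter retained %d genes", len(retained))

    groups = {c: list(class_of.index[class_of == c]) for c in sorted(class_of.unique())}
    class_tables: dict[str, dict[str, ExpressologTable]] = {}
    for other, prof in profiles.items():
        if other == focal:
            continue
        class_tables[other] = {}
        for cls, cts in groups.items():
            class_tables[other][cls] = expressolog_scores(
                profiles[focal], prof, orthology, cell_type_subset=cts, group=cls
            )
    flagged, detail = class_divergence(class_tables, config.expressolog_threshold, config.pair_rule)
    expr_divergent = pd.Index(flagged).intersection(retained)
    log.info("%d expression-divergent genes after the class filter", len(expr_divergent))

    tables: dict[tuple[str, str], ConservationTable] = {}
    for i, na in enumerate(networks):
        for nb in networks[i + 1:]:
            tab = conservation_scores(na, nb, orthology, k=config.k)
            tables[(tab.species_a, tab.species_b)] = tab
    cons = conservation_test(
        tables, focal, alpha=config.alpha, genes=expr_divergent,
        exact_max_group=config.exact_max_group,
    )

    universe = retained
    report = pd.DataFrame(index=universe.sort_values())
    report["expression_divergent"] = report.index.isin(expr_divergent)
    report = report.join(detail, how="left")
    report = report.join(cons, how="left")
    sig = report["significant"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    report["call"] = np.where(
        report["expression_divergent"] & sig,
        "focal-lineage-divergent",
        np.where(report["expression_divergent"], "expression-divergent", "conserved"),
    )
    summary = {
        "n_genes": int(len(universe)),
        "n_expression_divergent": int(report["expression_divergent"].sum()),
        "n_focal_lineage_divergent": int((report["call"] == "focal-lineage-divergent").sum()),
        "focal_species": focal,
    }
    return DivergenceReport(report, config, summary)
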