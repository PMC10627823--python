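"""End-to-end orchestration of the comparative workflow on synthetic data.

Stages: simulate multi-species data -> highly variable genes ->
neighbor-voting replicability -> consensus taxonomy -> pseudobulk and
expressolog scores -> aggregate co-expression networks -> co-expression
conservation -> divergence screen.  Every stage is also callable on its
own through the library API.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import conservation as cons_mod
from . import networks as net_mod
from . import screen as screen_mod
from . import simulate as sim_mod
from . import taxonomy as tax_mod
from . import voting
from .config import PipelineConfig
from .datasets import CellPopulationDataset
from .expressolog import expressolog_scores, pseudobulk

__all__ = ["run_all", "consensus_class_map"]

log = logging.getLogger(__name__)


def consensus_class_map(
    datasets: Sequence[CellPopulationDataset], taxonomy: tax_mod.ConsensusTaxonomy
) -> pd.Series:
    """Class label per consensus cell type, by majority over member clusters."""
    rows = []
    for ds in datasets:
        meta = ds.cell_meta[["cluster", "class_label"]].drop_duplicates()
        for _, r in meta.iterrows():
            node = f"{ds.name}|{r['cluster']}"
            cid = taxonomy.assignment.get(node)
            if pd.notna(cid):
                rows.append({"consensus": cid, "class_label": r["class_label"]})
    frame = pd.DataFrame(rows)
    return frame.groupby("consensus")["class_label"].agg(lambda s: s.mode().iloc[0])


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full pipeline; optionally write every artefact to ``outdir``.

    Outputs are written only after all stages succeed, so a failed run
    leaves no partial files behind.
    """
    datasets, orthology, truth = sim_mod.simulate_dataset(config.simulation)
    hvg = voting.select_variable_genes(datasets, orthology, config.n_hvg)

    rep_best = voting.replicability(datasets, level="cluster", mode="one_vs_best", hvg=hvg)
    rep_all = voting.replicability(datasets, level="cluster", mode="one_vs_all", hvg=hvg)
    taxonomy = tax_mod.build_consensus(rep_best, config.auroc_threshold)
    taxonomy = tax_mod.assign_ambiguous(taxonomy, rep_all)
    shared = tax_mod.shared_consensus(taxonomy)

    profiles = {ds.species: pseudobulk(ds, taxonomy) for ds in datasets}
    focal = config.focal_species or config.simulation.species_names[
        config.simulation.focal_species_index
    ]
    expr_tables = {
        other: expressolog_scores(profiles[focal], prof, orthology)
        for other, prof in profiles.items()
        if other != focal
    }

    net_hvg = hvg[: config.network_hvg]
    sn_networks = {
        ds.species: net_mod.build_species_network(
            ds, net_hvg, pool_size=config.pool_size, seed=config.seed
        )
        for ds in datasets
    }
    sn_conservation = {
        other: cons_mod.conservation_scores(
            sn_networks[focal], sn_networks[other], orthology, k=config.k
        )
        for other in sn_networks
        if other != focal
    }

    bulk_networks = sim_mod.simulate_bulk_networks(
        config.simulation, config.n_bulk_species, seed=config.seed
    )
    class_map = consensus_class_map(datasets, taxonomy)
    screen_cfg = screen_mod.ScreenConfig(
        focal_species=focal,
        expression_percentile=config.expression_percentile,
        expressolog_threshold=config.expressolog_threshold,
        k=config.k,
        alpha=config.alpha,
    )
    report = screen_mod.run_screen(profiles, bulk_networks, orthology, class_map, screen_cfg)

    results = {
        "datasets": datasets,
        "orthology": orthology,
        "truth": truth,
        "hvg": hvg,
        "replicability_best": rep_best,
        "replicability_all": rep_all,
        "taxonomy": taxonomy,
        "shared_consensus": shared,
        "profiles": profiles,
        "expressolog": expr_tables,
        "sn_networks": sn_networks,
        "sn_conservation": sn_conservation,
        "bulk_networks": bulk_networks,
        "report": report,
    }
    if outdir is not None:
        _write_outputs(results, config, Path(outdir))
    return results


def _write_outputs(results: dict, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    for ds in results["datasets"]:
        ds.write_mtx(outdir / f"counts_{ds.species}")
    results["orthology"].to_tsv(outdir / "orthology.tsv")
    results["truth"].to_json(outdir / "ground_truth.json")
    results["replicability_best"].to_tsv(outdir / "replicability_one_vs_best.tsv")
    results["taxonomy"].to_tsv(outdir / "consensus_taxonomy.tsv")
    for other, tab in results["expressolog"].items():
        tab.to_tsv(outdir / f"expressolog_{tab.species_a}_vs_{other}.tsv")
    for species, net in results["sn_networks"].items():
        net.write_h5(outdir / f"network_{species}.h5")
    for other, tab in results["sn_conservation"].items():
        tab.to_tsv(outdir / f"conservation_{tab.species_a}_vs_{other}.tsv")
    results["report"].to_tsv(outdir / "divergence_report.tsv")
    results["report"].to_json(outdir / "divergence_summary.json")
    pd.Series(results["hvg"]).to_csv(outdir / "hvg.tsv", sep="\t", index=False, header=["gene_id"])
    log.info("wrote pipeline outputs to %s", outdir)
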