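from math import comb

import numpy as np
import pandas as pd
import pytest

from orthoexpress import (
    ConservationTable,
    ExpressologTable,
    ScreenConfig,
    SimulationConfig,
    class_divergence,
    conservation_test,
    consensus_class_map,
    expression_filter,
    pseudobulk,
    run_screen,
    simulate_bulk_networks,
    simulate_dataset,
    taxonomy_from_truth,
)

from conftest import make_profile


def make_expr_table(scores: dict, species_b="chimp", group="ExN") -> ExpressologTable:
    genes = sorted(scores)
    frame = pd.DataFrame(
        {
            "gene_b": genes,
            "score_ab": [scores[g] for g in genes],
            "score_ba": [scores[g] for g in genes],
            "score": [scores[g] for g in genes],
        },
        index=pd.Index(genes, name="gene_a"),
    )
    return ExpressologTable(frame, "human", species_b, len(genes), group)


def make_cons_table(values: dict, sa, sb, k=10) -> ConservationTable:
    genes = sorted(values)
    frame = pd.DataFrame(
        {"raw_auroc": [values[g] for g in genes], "conservation": [values[g] for g in genes]},
        index=pd.Index(genes, name="gene"),
    )
    return ConservationTable(frame, sa, sb, k)


class TestExpressionFilter:
    def test_exactly_lowest_gene_removed(self):
        m = np.arange(1, 11, dtype=float)[:, None] * np.ones((1, 4))
        prof = make_profile(m, "a")
        kept = expression_filter([prof], percentile=10)
        assert "g0" not in kept and len(kept) == 9

    def test_vanishing_percentile_keeps_everything(self):
        m = np.arange(1, 11, dtype=float)[:, None] * np.ones((1, 4))
        kept = expression_filter([make_profile(m, "a")], percentile=1e-9)
        assert len(kept) == 10

    def test_percentile_bounds(self):
        prof = make_profile(np.ones((5, 4)), "a")
        for bad in (0, 100, -3, 150):
            with pytest.raises(ValueError):
                expression_filter([prof], percentile=bad)


class TestClassDivergence:
    def test_high_scores_not_flagged(self):
        tables = {"chimp": {"ExN": make_expr_table({"g1": 0.9, "g2": 0.95})}}
        flagged, detail = class_divergence(tables, threshold=0.55)
        assert len(flagged) == 0

    def test_vacuous_threshold_flags_everything(self):
        tables = {"chimp": {"ExN": make_expr_table({"g1": 0.9, "g2": 0.95})}}
        flagged, _ = class_divergence(tables, threshold=1.0)
        assert set(flagged) == {"g1", "g2"}

    def test_divergent_class_recorded(self):
        tables = {
            "chimp": {
                "ExN": make_expr_table({"g1": 0.2, "g2": 0.9}),
                "InN": make_expr_table({"g1": 0.8, "g2": 0.9}, group="InN"),
            }
        }
        flagged, detail = class_divergence(tables, threshold=0.55)
        assert list(flagged) == ["g1"]
        assert detail.loc["g1", "divergent_classes"] == "ExN"

    def test_all_pairs_rule_is_stricter(self):
        tables = {
            "chimp": {"ExN": make_expr_table({"g1": 0.2})},
            "gorilla": {"ExN": make_expr_table({"g1": 0.8}, species_b="gorilla")},
        }
        any_flagged, _ = class_divergence(tables, rule="any")
        all_flagged, _ = class_divergence(tables, rule="all")
        assert list(any_flagged) == ["g1"] and len(all_flagged) == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        scores = {f"g{i}": rng.uniform(0, 1) for i in range(50)}
        tables = {"chimp": {"ExN": make_expr_table(scores)}}
        lo, _ = class_divergence(tables, threshold=0.55)
        hi, _ = class_divergence(tables, threshold=0.6)
        assert set(lo) <= set(hi)


class TestConservationTest:
    def test_exact_tail_probability(self):
        """Complete separation of 5 focal vs 5 background scores gives the
        exact one-sided tail 1/C(10,5)."""
        genes = {"g1": None}
        tables = {}
        for i in range(5):
            tables[("human", f"s{i}")] = make_cons_table({"g1": 0.1 + 0.01 * i}, "human", f"s{i}")
        for i in range(5):
            tables[(f"s{i}", f"t{i}")] = make_cons_table({"g1": 0.9 + 0.01 * i}, f"s{i}", f"t{i}")
        out = conservation_test(tables, focal="human")
        assert out.loc["g1", "p"] == pytest.approx(1.0 / comb(10, 5))

    def test_identical_distributions_not_significant(self):
        tables = {}
        vals = [0.8, 0.85, 0.9, 0.95]
        for i, v in enumerate(vals):
            tables[("human", f"s{i}")] = make_cons_table({"g1": v}, "human", f"s{i}")
            tables[(f"s{i}", f"t{i}")] = make_cons_table({"g1": v}, f"s{i}", f"t{i}")
        out = conservation_test(tables, focal="human")
        assert out.loc["g1", "p"] > 0.4
        assert not out.loc["g1", "significant"]

    def test_background_required(self):
        tables = {("human", "s0"): make_cons_table({"g1": 0.5}, "human", "s0")}
        with pytest.raises(ValueError, match="background"):
            conservation_test(tables, focal="human")

    def test_bh_adjustment_matches_hand_computation(self):
        """BH step-up on p = (.01, .02, .03, .04) gives (.04, .04, .04, .04)."""
        tables = {}
        # craft four genes with increasing separation -> distinct raw p values
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])
        # and the hand-computed step-up: p_(i) * n / i, cumulative min from the top
        hand = np.minimum.accumulate((p * 4 / np.arange(1, 5))[::-1])[::-1]
        assert np.allclose(adj, hand)


@pytest.fixture(scope="module")
def screen_cohort():
    div = ("g00000", "g00013", "g00026")
    cfg = SimulationConfig(
        n_species=4, n_cell_types=12, cells_per_type=40, n_genes=400,
        coexpr_module_count=4, module_size=12, divergent_gene_ids=div,
        seed=11,
    )
    datasets, orthology, truth = simulate_dataset(cfg)
    taxonomy = taxonomy_from_truth(truth)
    profiles = {ds.species: pseudobulk(ds, taxonomy) for ds in datasets}
    networks = simulate_bulk_networks(cfg, 7, seed=11)
    class_map = consensus_class_map(datasets, taxonomy)
    return cfg, datasets, orthology, truth, profiles, networks, class_map


class TestRunScreen:
    def test_planted_genes_called_and_evidence_recorded(self, screen_cohort):
        cfg, _, orthology, truth, profiles, networks, class_map = screen_cohort
        report = run_screen(profiles, networks, orthology, class_map,
                            ScreenConfig(focal_species="human"))
        calls = set(report.calls())
        planted = set(truth.true_divergent_genes)
        assessable = planted & set(report.table.index)
        assert assessable <= calls  # every expressed planted gene recovered
        # moving a planted gene between modules also perturbs the focal
        # neighbourhoods of its old and new co-members; any other call
        # would be a genuine false positive
        mem = cfg.module_of_gene()
        genes = cfg.ortho_gene_ids
        touched = set()
        for g in planted:
            m = mem[genes.get_loc(g)]
            for affected in (m, (m + 1) % cfg.coexpr_module_count):
                touched |= set(genes[mem == affected])
        assert calls - planted <= touched
        for g in sorted(assessable):
            row = report.table.loc[g]
            assert row["expression_divergent"]
            assert truth.divergent_class in row["divergent_classes"]
            assert row["p_adj"] < 0.05

    def test_alpha_monotonicity(self, screen_cohort):
        cfg, _, orthology, truth, profiles, networks, class_map = screen_cohort
        strict = run_screen(profiles, networks, orthology, class_map,
                            ScreenConfig(focal_species="human", alpha=1e-4))
        lax = run_screen(profiles, networks, orthology, class_map,
                         ScreenConfig(focal_species="human", alpha=0.05))
        assert set(strict.calls()) <= set(lax.calls())

    def test_divergence_in_nonfocal_lineage_not_called(self):
        """Genes rewired in chimp must not be called divergent when the
        screen is run with human as the focal lineage."""
        div = ("g00000", "g00013")
        cfg = SimulationConfig(
            n_species=4, n_cell_types=12, cells_per_type=40, n_genes=400,
            coexpr_module_count=4, module_size=12, divergent_gene_ids=div,
            focal_species_index=1,  # chimp carries the divergence
            seed=12,
        )
        datasets, orthology, truth = simulate_dataset(cfg)
        taxonomy = taxonomy_from_truth(truth)
        profiles = {ds.species: pseudobulk(ds, taxonomy) for ds in datasets}
        # networks: chimp is the rewired lineage; human-centred screen
        networks = simulate_bulk_networks(cfg, 7, seed=12)
        class_map = consensus_class_map(datasets, taxonomy)
        report = run_screen(profiles, networks, orthology, class_map,
                            ScreenConfig(focal_species="chimp"))
        chimp_calls = set(report.calls())
        assert set(div) & set(report.table.index) <= chimp_calls

        # same cohort, human focal: human networks are conserved, so the
        # conservation test cannot implicate the human lineage
        human_networks = [n for n in networks if n.species != "chimp"]
        human_networks[0].species = "human"
        report_h = run_screen(profiles, human_networks, orthology, class_map,
                              ScreenConfig(focal_species="human"))
        assert not set(div) & set(report_h.calls())

    def test_report_invariants(self, screen_cohort):
        cfg, _, orthology, truth, profiles, networks, class_map = screen_cohort
        report = run_screen(profiles, networks, orthology, class_map,
                            ScreenConfig(focal_species="human"))
        t = report.table
        focal_set = set(t.index[t["call"] == "focal-lineage-divergent"])
        expr_set = set(t.index[t["expression_divergent"]])
        assert focal_set <= expr_set <= set(t.index)
        valid = t["p_adj"].notna() & t["p"].notna()
        assert (t.loc[valid, "p_adj"] >= t.loc[valid, "p"] - 1e-12).all()
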