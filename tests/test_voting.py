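import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from orthoexpress import (
    gene_set_replicability,
    permutation_threshold_check,
    replicability,
    select_variable_genes,
)

from conftest import make_dataset


@pytest.fixture(scope="module")
def pair_datasets(small_sim):
    datasets, orthology, _ = small_sim
    return datasets[:2], orthology


def _brute_force_replicability(ds_train, ds_test, hvg, level_col="cluster"):
    """Independent re-derivation: explicit Spearman votes and pair-counting
    AUROC (no mid-rank shortcut on the package path)."""

    def cell_ranks(ds):
        x = ds.subset_genes(hvg).dense_counts()
        return np.column_stack([rankdata(x[:, c]) for c in range(x.shape[1])])

    rtr, rte = cell_ranks(ds_train), cell_ranks(ds_test)
    lab_tr = ds_train.cell_meta[level_col].to_numpy()
    lab_te = ds_test.cell_meta[level_col].to_numpy()
    out = {}
    for t_tr in sorted(set(lab_tr)):
        # vote of a test cell = mean Spearman correlation with the train type's cells
        votes = []
        members_tr = np.flatnonzero(lab_tr == t_tr)
        for c in range(rte.shape[1]):
            cors = [np.corrcoef(rte[:, c], rtr[:, m])[0, 1] for m in members_tr]
            votes.append(np.mean(cors))
        votes = np.asarray(votes)
        for t_te in sorted(set(lab_te)):
            pos = votes[lab_te == t_te]
            neg = votes[lab_te != t_te]
            gt = sum((p > n) for p in pos for n in neg)
            eq = sum(np.isclose(p, n) for p in pos for n in neg)
            out[(t_tr, t_te)] = (gt + 0.5 * eq) / (len(pos) * len(neg))
    return out


def test_one_vs_all_matches_brute_force_oracle(pair_datasets):
    datasets, _ = pair_datasets
    # small slice: 2 datasets, few cells, <=50 genes
    small = [ds.subset_genes(ds.gene_ids[:40]) for ds in datasets]
    small = [
        type(ds)(ds.counts[:, :90], ds.gene_ids, ds.cell_meta.iloc[:90], ds.name)
        for ds in small
    ]
    hvg = small[0].gene_ids
    rep = replicability(small, level="cluster", mode="one_vs_all", hvg=hvg)
    oracle = _brute_force_replicability(small[0], small[1], hvg)
    for (t_tr, t_te), expected in oracle.items():
        got = rep.scores.loc[f"{small[0].name}|{t_tr}", f"{small[1].name}|{t_te}"]
        assert got == pytest.approx(expected, abs=1e-9)


def test_self_comparison_diagonal_is_one(small_sim):
    datasets, _, _ = small_sim
    ds = datasets[0]
    copy = type(ds)(ds.counts, ds.gene_ids, ds.cell_meta.copy(), "copy")
    rep = replicability([ds, copy], level="cluster", mode="one_vs_all", hvg=ds.gene_ids)
    for cl in sorted(ds.cell_meta["cluster"].unique()):
        assert rep.scores.loc[f"{ds.name}|{cl}", f"copy|{cl}"] == pytest.approx(1.0)


def test_permuted_labels_mean_auroc_near_half(small_sim):
    """Randomly permuted cluster labels carry no class signal: over many
    permutations the mean one_vs_all AUROC sits at chance level."""
    datasets, _, _ = small_sim
    rng = np.random.default_rng(0)
    small = [
        type(ds)(ds.counts[:, :120], ds.gene_ids, ds.cell_meta.iloc[:120], ds.name)
        for ds in datasets[:2]
    ]
    means = []
    for _ in range(20):
        permuted = []
        for ds in small:
            meta = ds.cell_meta.copy()
            meta["cluster"] = rng.permutation(meta["cluster"].to_numpy())
            permuted.append(type(ds)(ds.counts, ds.gene_ids, meta, ds.name))
        rep = replicability(permuted, level="cluster", mode="one_vs_all",
                            hvg=small[0].gene_ids[:100])
        means.append(np.nanmean(rep.scores.to_numpy(dtype=float)))
    assert abs(np.mean(means) - 0.5) < 0.02


def test_one_vs_best_scores_best_above_second(small_sim):
    datasets, _, _ = small_sim
    rep = replicability(datasets[:2], level="cluster", mode="one_vs_best",
                        hvg=datasets[0].gene_ids[:150])
    for train in rep.scores.index:
        row = rep.scores.loc[train].dropna()
        if row.empty:
            continue
        meta = rep.node_meta.set_index("node")
        for ds_name, grp in row.groupby(meta.loc[row.index, "dataset"].to_numpy()):
            assert len(grp) == 2  # only the two closest neighbours are scored
            assert grp.max() >= 0.5 >= grp.min()
            assert grp.max() + grp.min() == pytest.approx(1.0)


def test_monotone_transform_invariance(small_sim):
    """Votes are Spearman correlations of per-cell ranks, so any strictly
    monotone transform of expression leaves every AUROC unchanged."""
    datasets, _, _ = small_sim
    small = [
        type(ds)(ds.counts[:50, :80], ds.gene_ids[:50], ds.cell_meta.iloc[:80], ds.name)
        for ds in datasets[:2]
    ]
    hvg = small[0].gene_ids
    rep = replicability(small, mode="one_vs_all", hvg=hvg)
    transformed = [
        type(ds)(np.asarray(ds.dense_counts()) ** 1.5 * 3.0, ds.gene_ids, ds.cell_meta, ds.name)
        for ds in small
    ]
    rep_t = replicability(transformed, mode="one_vs_all", hvg=hvg)
    pd.testing.assert_frame_equal(rep.scores, rep_t.scores)


def test_permutation_threshold_check():
    """In the large-sample regime, shuffled cluster labels produce no
    cross-species one_vs_best hits above 0.6, while a permissive 0.51
    threshold lets chance hits through."""
    from orthoexpress import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n_species=2, n_cell_types=6, cells_per_type=250,
                           n_genes=150, coexpr_module_count=2, module_size=10, seed=5)
    datasets, _, _ = simulate_dataset(cfg)
    hvg = datasets[0].gene_ids[:120]
    assert permutation_threshold_check(datasets, n_perms=10, threshold=0.6,
                                       hvg=hvg, seed=0) == 0
    assert permutation_threshold_check(datasets, n_perms=10, threshold=0.51,
                                       hvg=hvg, seed=0) > 0
    # an impossible threshold can never be exceeded
    assert permutation_threshold_check(datasets, n_perms=1, threshold=1.01,
                                       hvg=hvg, seed=0) == 0
    with pytest.raises(ValueError):
        permutation_threshold_check(datasets, n_perms=0)


class TestSelectVariableGenes:
    def test_single_dataset_all_genes(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.poisson(5, size=(20, 30)), "a", ["x", "y"] * 15)
        hvg = select_variable_genes([ds], None, n_genes=20)
        assert set(hvg) == set(ds.gene_ids)

    def test_constant_gene_excluded(self):
        """Zero variance in any one dataset disqualifies a gene: it cannot
        be variable in every dataset."""
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(10, 20))
        counts[3, :] = 7  # constant in this dataset only
        ds_a = make_dataset(counts, "a", ["x", "y"] * 10)
        ds_b = make_dataset(rng.poisson(5, size=(10, 20)), "b", ["x", "y"] * 10)
        hvg = select_variable_genes([ds_a, ds_b], None, n_genes=10)
        assert "g3" not in hvg

    def test_top_ranked_by_documented_criterion(self, small_sim):
        """The selection equals a brute-force recomputation of the binned
        variance-rank criterion."""
        datasets, orthology, _ = small_sim
        n = 50
        hvg = select_variable_genes(datasets, orthology, n_genes=n, n_bins=10)

        shared = datasets[0].gene_ids
        for ds in datasets[1:]:
            shared = shared.intersection(ds.gene_ids)
        shared = pd.Index(sorted(shared))
        scores, detected = [], np.ones(len(shared), bool)
        for ds in datasets:
            sub = ds.subset_genes(shared)
            x = sub.cpm()
            mean, var = x.mean(axis=1), x.var(axis=1)
            detected &= (var > 0) & (sub.dense_counts().var(axis=1) > 0)
            bins = np.floor((rankdata(mean) - 1) / len(mean) * 10).astype(int)
            s = np.empty(len(mean))
            for b in np.unique(bins):
                m = bins == b
                s[m] = rankdata(var[m]) / m.sum()
            scores.append(s)
        crit = np.median(scores, axis=0)
        frame = pd.DataFrame({"gene": shared, "crit": crit})[detected]
        expected = frame.sort_values(["crit", "gene"], ascending=[False, True]).head(n)["gene"]
        assert list(hvg) == list(expected)


def test_gene_set_replicability(small_sim):
    datasets, orthology, _ = small_sim
    hvg = datasets[0].gene_ids[:60]
    sets = {
        "all_hvg": list(hvg),
        "tiny": list(hvg[:3]),  # below the 5-gene floor -> skipped
    }
    out = gene_set_replicability(datasets[:2], sets, level="subclass")
    assert "tiny" not in out.index
    assert out.loc["all_hvg", "n_genes"] == 60
    # restriction to the full gene universe reproduces plain replicability
    rep = replicability(datasets[:2], level="subclass", mode="one_vs_all", hvg=hvg)
    meta = rep.node_meta.set_index("node")
    matched = [
        rep.scores.loc[tr, te]
        for tr in rep.scores.index
        for te in rep.scores.columns
        if np.isfinite(rep.scores.loc[tr, te])
        and meta.loc[tr, "label"] == meta.loc[te, "label"]
        and meta.loc[tr, "species"] != meta.loc[te, "species"]
    ]
    assert out.loc["all_hvg", "cross_auroc"] == pytest.approx(np.mean(matched))
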