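# Methods

This note documents the models, conventions and design choices behind
`orthoexpress`, and what the synthetic benchmarks do and do not show.

## Synthetic multi-species generator

`simulate_dataset` draws, per species, a genes × cells count matrix around
latent cell-type × gene means shared across species:

* **Latent means.** Gene g has a baseline log-expression b_g ~ N(0, 1.2²)
  shared by all species. Its cell-type profile is
  E_s[g, t] = √ρ · Z[g, t] + √(1−ρ) · ε_s[g, t] with Z shared and ε
  species-specific (both N(0, profile_sd²), default 1.5). ρ =
  `profile_conservation` is therefore the correlation of log latent
  profiles between any two species; ρ = 1 gives identical profiles, ρ = 0
  independent ones. Negative ρ is only self-consistent for two species and
  is rejected otherwise.
* **Counts.** Within a cell, gene rates exp(b + E) are normalized to
  proportions, scaled by a Gamma-distributed library size (mean
  `library_size_mean`, default 5,000 counts), and drawn from a negative
  binomial with common dispersion d (variance μ + dμ²; d = 0 degrades to
  Poisson). This is the standard overdispersed count model for snRNA-seq;
  the data the pipeline targets motivate no more structure than that.
* **Co-expression modules.** `coexpr_module_count` disjoint blocks of
  `module_size` genes each share a per-cell latent factor added to their
  log-rates (loading `module_strength`). The factor is drawn per cell, so
  any downstream pooling of nuclei into pseudobulk samples inherits the
  module correlation regardless of how the pools are drawn.
* **Planted divergence.** Each gene in `divergent_gene_ids` is rewired in
  the focal lineage only: its cell-type means within `divergent_class` are
  permuted, and its module membership moves to the next module. The
  default permutation (`divergence_mode="reverse"`) assigns the largest
  mean to the cell type that had the smallest — it preserves the multiset
  of expression magnitudes (so the expression filter is unaffected) while
  forcing a strongly negative within-class profile correlation. A cyclic
  shift is available but decorrelates only weakly, making planted
  divergence statistically invisible in small classes.
* **Known side effect.** Moving a planted gene between modules also
  changes the focal-lineage neighbourhoods of its old and new co-members
  by one gene. With enough statistical power the screen legitimately picks
  some of these up; recovery benchmarks score them separately from the
  planted genes.

`simulate_bulk_networks` emulates externally supplied aggregate bulk
co-expression networks: one rewired network for the focal lineage plus
`n_extra_species` conserved outgroup networks, built by Spearman
correlation over Gaussian samples carrying the same module structure and
rank-standardized exactly as the cell-type networks are. At least two
outgroups are required, since the screen needs a background of
non-focal species pairs.

**What the generator does not emulate:** doublets, ambient RNA, batch and
donor structure, cell-type abundance differences, and isoform-level
variation beyond splitting gene counts among pseudo-isoforms. Passing
recovery benchmarks therefore demonstrates correctness of the inference
machinery under the stated noise model, not robustness to real-data
artefacts.

## Neighbor voting

Votes use the closed-form "fast" kernel: per-cell mid-ranks over the
highly variable genes, centered and scaled to unit norm, so dot products
are Spearman correlations and a test cell's vote for a training type is
its mean similarity to that type's cells. AUROCs use mid-rank ties
throughout, which makes them exactly equal to a Mann–Whitney U oracle.
In `one_vs_best`, the two closest test types per training type are chosen
by mean vote with lexicographic tie-breaking (logged); the closer
neighbour always holds the larger of the two complementary scores. Cell
types with fewer than two cells are reported missing with a warning.

Highly variable genes are selected per dataset by variance rank within ten
equal-occupancy mean-expression bins, requiring non-zero variance in every
dataset, and combined across datasets by median within-bin rank; ties
break by gene identifier, so selection is deterministic.

The label-permutation check shuffles within-dataset cluster labels and
counts cross-dataset `one_vs_best` scores above a threshold. Because the
best/second-best choice selects extreme order statistics of noisy group
means, small clusters inflate the null scores; the check is meaningful in
the large-cluster regime (hundreds of cells per cluster), where a 0.6
threshold yields no hits while 0.51 admits chance hits.

## Consensus taxonomy

Nodes are (species, cluster); edges join reciprocal best hits (mutual
top-1 by `one_vs_best` score per species pair) or pairs where either
directional AUROC exceeds the threshold (default 0.6). Components touching
at least two species become consensus types; the rest are ambiguous and
are rescued by a strict majority (> k/2) of their top-k one_vs_all
neighbours (k = 10, then 20). Neighbour similarity is the mean of the two
directional scores; neighbours are counted per (species, cluster) node.
Raising the threshold only removes edges, so components can split but
never merge.

## Expressolog scores

Pseudobulk profiles are per-cell CPM averaged within each consensus type
(no log transform by default; the correlation is computed on the CPM
scale, with a log1p option exposed). Correlation ranks ascend, so the
best-matching candidate has rank N and the formula (r−1)/(N−1) maps it to
AUROC 1. Ties take mid-ranks; genes with zero variance over the
(sub)group's cell types have undefined correlations and receive the median
rank, with a logged count. Group-restricted scores (per class, subclass or
meta-cluster) correlate over the group's cell types only but always rank
within the full N-gene universe, and require at least three shared cell
types.

Isoform self-prediction applies three filters — cell types backed by ≥ 10
nuclei in both species, isoforms with total expression ≥ 5 (TPM scale) in
both species, genes with ≥ 2 isoforms shared by both species — then ranks
each isoform's cross-species self-score among its siblings; identical
siblings give exactly 0.5 under mid-ranks.

## Co-expression networks

Cell-type networks use Spearman correlation across disjoint random pools
of `pool_size` nuclei (default 20; remainder nuclei are dropped so pool
depth is constant; fewer than two pools skips the cell type with a
warning). Correlations are rounded to 9 decimals before ranking so that
theoretically tied values share a mid-rank regardless of floating-point
evaluation order. Rank-standardization runs over the upper-triangle pairs
only and is mirrored; the diagonal is fixed to 1 and excluded from
ranking; undefined correlations are set to exactly 0.5 (the median rank).
Aggregation is the element-wise mean, which preserves bounds, symmetry
and permutation invariance of the component list.

## Co-expression conservation

Top-k partner sets (k = 10 by default) exclude the self-edge and include
all genes tied at the k-th weight (logged). The ranking population in the
target network excludes the target gene itself; if a mapped partner
coincides with the target it is dropped from the partner set. The
all-pairs AUROC matrix is computed as a sparse top-k indicator times a
column-ranked network — a contract test verifies it equals the per-pair
definition exactly. Specificity ranks the orthologue pairing's AUROC
within each direction's row separately, converts via (r−1)/(N−1) and
averages the directions.

## Divergence screen

* **Expression filter:** the floor(n·p/100) lowest-mean genes (cross-
  species mean pseudobulk expression) are removed — a count-based rule, so
  p → 0 retains everything and p = 10 over ten genes removes exactly the
  lowest.
* **Class filter:** a gene is expression-divergent when its class-level
  expressolog score drops below 0.55 in at least one class for at least
  one focal-vs-other pair (default); an "all pairs" strict mode is
  available. Lineage specificity is *not* asserted here — that is the
  conservation test's job.
* **Conservation test:** per gene, a one-sided Wilcoxon rank-sum of
  conservation scores in focal-vs-other species pairs against all
  unordered non-focal pairs (configurable), exact null for group sizes up
  to 25 and normal approximation with continuity correction above;
  Benjamini–Hochberg adjustment across tested genes, significance at
  adjusted p < α (default 0.05).
* **Call:** focal-lineage-divergent = expression-divergent ∧ significant.

Because the class filter needs ≥ 3 cell types per class and the Wilcoxon
needs several background pairs, sensible cohorts have ≥ 9 cell types over
3 classes and ≥ 4 background species (≥ 6 non-focal pairs).

## Benchmark problem sizes

The bundled benchmarks run at desk scale: cohorts of 2,000 genes × 21 cell
types × 50 cells per type across 5 species for screen recovery (with a
background of 7 outgroup networks), 600 genes × 10 types × 5 species for
taxonomy recovery, 2,000 genes × 20 cell types × 20 replicates for null
calibration, and ≤ 50-gene instances for the brute-force oracle
equivalences. The screen-recovery fixture plants 15 divergent genes; since
planting preserves expression magnitude, each planted gene falls into the
removed bottom expression decile with ~10% probability and is then
unassessable by construction, which bounds the expected end-to-end recall
near 0.9.

## Known limitations

* The expressolog and conservation scores are rank statistics: they
  measure specificity relative to the gene universe supplied and shift if
  that universe is heavily filtered.
* The screen's background pairing set ("all non-focal pairs") treats pair
  scores as exchangeable, ignoring the dependence induced by shared
  species; the exact Wilcoxon p-values are therefore approximate in their
  independence assumption, as in the workflow the screen follows.
* Group-level expressolog scores with constant within-group profiles fall
  back to the median rank rather than excluding the gene; the count of
  affected genes is logged.
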