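# orthoexpress

Comparative single-cell transcriptomics across species: build a consensus
cross-species cell-type taxonomy, score how well 1:1 orthologues conserve
their expression profiles over matched cell types ("expressolog" scores),
aggregate cell-type-specific co-expression networks, quantify cross-species
conservation of co-expression neighbourhoods, and screen for genes whose
expression **and** co-expression diverge in exactly one lineage (for
example, human-specific regulatory divergence among primates).

The package is aimed at researchers comparing single-nucleus RNA-seq
atlases of homologous tissues across species. It ships a synthetic
multi-species data generator with planted ground truth, so the entire
workflow is testable end to end without any external data.

## The statistics at the core

**Neighbor-voting replicability.** Each cell is rank-standardized over a
shared set of highly variable genes; a test cell's vote for a training
cell type is its mean Spearman similarity to that type's cells. The
replicability of a candidate test cell type is the AUROC of its member
cells' votes against a comparison population — all other cells
(`one_vs_all`) or only the second-closest cell type (`one_vs_best`, a
stricter specificity measure). Within-species clusters that are reciprocal
best hits or exceed AUROC 0.6 in `one_vs_best` are linked; connected
components of that graph are the consensus cross-species cell types.

**Expressolog score.** For species pair (A, B) with N shared 1:1
orthologues, every gene's pseudobulk profile (mean CPM over shared
consensus cell types) is Pearson-correlated against all N genes of the
other species. With r_ij the ascending rank of the correlation of gene i
with gene j among the N candidates,

    AUROC = (r_ij − 1) / (N − 1),

and the expressolog score of an orthologue pair is the average of the two
directional AUROCs: 1 means the orthologue is the single best expression
match, 0.5 means unrelated profiles, 0 means extreme divergence.

**Co-expression conservation.** Species networks are averages of
rank-standardized Spearman networks built per cell type from pseudobulk
pools of 20 nuclei. For a gene pairing (i, j) across two networks, i's
top-10 partners are located in the ranking of co-expression with j in the
other network (AUROC, both directions averaged); the conservation score is
the specificity of the orthologue pairing — its rank among all N pairings,
scaled to [0, 1].

**Divergence screen.** Drop the bottom expression percentile; flag genes
with a class-level expressolog score < 0.55 against another species; keep
genes whose conservation between the focal lineage and other species is
significantly lower than between pairs of other species (one-sided
Wilcoxon rank-sum, Benjamini–Hochberg adjusted).

## Worked example

```bash
python examples/02_consensus_taxonomy.py
```

```
10 consensus cell types from 50 within-species clusters
10 consensus types present in all 5 species
adjusted Rand index vs planted homology: 1.000
```

Five simulated species with ten shared latent cell types are clustered
into ten consensus types found in every species, and the recovered
partition matches the planted homology exactly (ARI = 1).

```bash
python examples/05_divergence_screen.py
```

```
expressed genes assessed:      360
expression-divergent (class score < 0.55): 31
focal-lineage-divergent calls: 9
planted genes recovered:       5 / 5
additional calls (focal co-expression partners of planted genes): 4
```

All five genes planted with human-specific profile and neighbourhood
rewiring are recovered; the extra calls are co-expression partners whose
focal neighbourhoods were altered as a side effect of the planted
rewiring. The other examples cover simulation (`01`), expressolog scoring
(`03`, mean score 0.992 between conserved species) and network
conservation (`04`, module genes 0.90 vs background 0.54).

A thin CLI mirrors the library (`orthoexpress simulate|replicability|
consensus|expressolog|networks|conservation|screen|all`); `orthoexpress
all --config demo.yaml --outdir run/` executes every stage from a YAML
configuration and writes TSV/JSON/HDF5 artefacts plus a log.

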