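# centrex

Imaging-transcriptomics pipeline linking **voxel-wise degree-centrality
abnormalities** in group-contrast maps to **regional gene expression** from a
multi-donor brain transcriptomic atlas.

In several neurological conditions, resting-state fMRI shows reorganization of
functional "hubness": some regions gain connections, others lose them. A
recurring question is whether the *physiological* spatial expression pattern
of disease-relevant genes (measured post-mortem in healthy donors, as in the
Allen Human Brain Atlas) predicts *where* these network changes appear.
`centrex` implements that analysis end to end for researchers in imaging
genomics, together with a synthetic-data generator that plants known effects
so every stage can be verified quantitatively without any external download.

## What it computes

1. **Degree centrality** — for each gray-matter voxel *i* of a subject,
   `DC(i) = #{ j ≠ i : r(i, j) > 0.25 }`, the number of other GM voxels whose
   time-series Pearson correlation exceeds 0.25 (positive correlations only;
   GM mask from thresholding a GM probability volume at 0.20). Maps are
   standardized within subject.
2. **Group GLM** — voxel-wise OLS of centrality on group + age + sex +
   scanner; one-sided t contrasts; cluster-extent thresholding (display:
   p < 0.001 uncorrected, k = 20, 18-connectivity) and a lenient p < 0.01 map
   used as the association input; minimum-statistic conjunctions.
3. **Donor-atlas preparation** — left-hemisphere restriction (x < 0), one
   representative probe per gene (least-skewed pooled distribution), per-donor
   z-scoring `z = (x_i − x̄)/σ`, and sampling of the contrast map as the mean
   of suprathreshold voxels inside a 5-mm cube centred on each tissue
   coordinate.
4. **Spatial association** — per gene, PCA across the donor dimension keeping
   components explaining ≥ 95 % of variance, weighted least squares of the
   image vector on those components (weights = contributing sample counts),
   reporting adjusted R² and the correlation sign; reliability via
   * the **chance likelihood** `CL = #(R²_perm > R²_obs) / 1000`, a bootstrap
     null that permutes the genomic rows against the image, and
   * the **donor autocorrelation**, the mean pairwise Pearson correlation of
     the gene's profile across donors.
   Genes pass when `CL < 0.001`, autocorrelation ≥ 0.2 and R²_adj ≥ 0.15.
5. **Enrichment** — upper-tail hypergeometric over-representation of the
   passing genes against gene-set collections, Bonferroni-corrected per
   namespace at α = 0.05.
6. **Cell-type profiling** — quantile normalization of a genes × (cell type ×
   replicate) matrix; per-type mean ± SEM (plus a 0.001 offset for log
   display), specificity and in/out enrichment.

The `simulate` module generates two-group fMRI cohorts with a planted,
spatially graded hub region, six-donor expression bundles in which a known
gene subset tracks the contrast map at a chosen effect size, gene sets with
one enriched set, and marker-structured cell-type matrices — all with truth
labels returned.

## Worked example

```bash
centrex run-all --seed 7 --out results/demo
```

runs the full pipeline on the default synthetic study (40 subjects,
10×10×10 voxels at 2 mm, 6 donors × 800 samples, 100 genes of which 20 are
coupled to the contrast map) and prints

```json
{
  "n_passing": 19,
  "coupled_gene_recovery_rate": 0.95,
  "null_pass_rate": 0.0,
  "planted_set_label": "SET_PLANTED",
  "n_display_clusters": 1
}
```

i.e. the patients-vs-controls contrast yields one surviving display cluster
(the planted hub), 19 of the 20 planted genes pass the full association
filter, and no null gene does. `results/demo/associations.tsv` holds the
per-gene statistics, e.g.

```text
gene      r2_adjusted  direction  chance_likelihood  autocorrelation  n_components  passes_filter
GENE0000  0.3634       1          0.0                0.9342           2             True
```

— an adjusted R² of 0.36 against the centrality t-map, a chance likelihood of
0 (no permutation of the genomic data matched the observed fit), and a donor
autocorrelation of 0.93 (the spatial profile reproduces across donors).
Downstream files contain the Bonferroni-corrected enrichment of the planted
set and cell-type profiles of the passing genes; each output carries a JSON
provenance sidecar (config, seed, input hashes).

Every stage is also available as a library function
(`centrex.centrality.degree_centrality`, `centrex.glm.fit_voxelwise_glm`,
`centrex.association.gene_association`, ...) and as individual subcommands
(`simulate`, `centrality`, `glm`, `associate`, `enrich`, `celltype`).

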