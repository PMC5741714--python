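# devtraj

Trajectory clustering of a developmental bulk RNA-seq time course (E15, P1,
P7, P15, P30) integrated with cell-type signatures derived from labeled
single-cell RNA data.

The pipeline:

1. **Differential expression** (`devtraj.de`) — a minimal negative-binomial
   Wald engine: median-of-ratios size factors, moment dispersion estimates
   shrunk toward a cross-gene trend, Benjamini–Hochberg adjustment within
   each comparison, and a one-sided conversion of adjusted p-values to
   signed Z-scores (adjusted p = 2.87e-7 corresponds to |Z| = 5).
2. **Trajectory clustering** (`devtraj.trajectory`) — transcripts with
   |Z| ≥ 5 in ≥ 2 of the 10 stage-pair comparisons are assembled into an
   m×10 signed-Z matrix; each value is discretized into 5 levels delimited
   by the 10th/30th/70th/90th percentiles; distinct discretized rows are
   *trajectories*, and those holding ≥ `min_el` (default 1%) of the rows
   set the cluster number k; k-means (squared Euclidean, 50 restarts) then
   partitions the original Z values, and every cluster's mean stage profile
   is classified as decreasing / increasing / transient.
3. **Marker discovery** (`devtraj.markers`) — all subtype pairs are compared
   (47 subtypes → 1081 DE tables); a gene is a subtype marker when it is
   significantly up-regulated in all but 2 of its 46 comparisons (44/46),
   with multi-subtype markers assigned to the subtype of highest expression;
   type-level markers must be homogeneous across their type's subtypes and
   up-regulated against every other type.  Combined per-type lists include
   nested subtype markers; everything unowned is the non-marker set.
4. **Enrichment** (`devtraj.enrich`) — hypergeometric tests with Bonferroni
   (marker enrichments) or Benjamini–Hochberg (gene-set enrichments)
   correction: marker-set enrichment per developmental cluster with top-3
   reporting, a term × cell-type interaction matrix with the non-marker
   depletion column, and direction-based splitting of annotated gene sets.
5. **Driver prediction** (`devtraj.drivers`) — drivers of a cell type are
   the exact intersection of its combined marker list with the
   decreasing-direction clusters, annotated with max-normalized 5-stage
   RPKM profiles.
6. **Synthetic data** (`devtraj.simulate`) — NB bulk counts with 13 planted
   temporal archetypes (5 decreasing / 4 increasing / 4 transient), sparse
   UMI single-cell counts with planted type/subtype markers over an
   11-type / 47-subtype hierarchy, and gene-set collections with controlled
   overlap, each returned together with its ground-truth table.

## CLI

```sh
devtraj run-all --seed 1 --outdir out            # full synthetic pipeline
devtraj cluster --seed 1 --outdir out            # through trajectory clustering
devtraj run-all --config config.yaml             # custom configuration
```

A YAML config can override simulation parameters, thresholds
(`z_threshold`, `min_comparisons`, `min_el`, `alpha`, `allowed_losses`,
`direction_threshold`, `term_alpha`), and supply external inputs
(`inputs: {bulk_counts, sample_sheet, sc_counts, cell_sheet, gmt}`) in the
documented TSV/GMT schemas in place of simulation.  All artifacts are plain
text (TSV/GMT/JSON); `manifest.json` records the config, seed and per-file
SHA-256 checksums, and reruns with the same config are byte-identical.

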