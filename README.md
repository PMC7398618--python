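# chromatlas

A reusable, tested implementation of the integrative analyses used to build
developmental chromatin atlases from tissue x stage epigenomic series:

- **`chromatlas.core`** — genomic interval algebra (BED-convention, 0-based
  half-open), readers/writers for the plain-text formats (BED/narrowPeak,
  dense segmentation BED4, TSV signal matrices keyed by
  `tissue:stage:replicate`), matrix transforms (quantile normalization,
  unit-vector rows, log2 with zero floor, FROT QC, correlation by stage
  separation) and shared statistics (BH adjustment, 2x2 chi-square, exact
  rate-ratio test, empirical-Bayes moderated t).
- **`chromatlas.synthetic`** — generators for every pipeline input (gene
  annotation, TADs, replicated chromatin-state segmentations, H3K27ac /
  ATAC / expression grids, peak sets, emission-model families, validation
  tables, motif occurrence matrices) with all planted structure recorded in
  a `SyntheticTruth` object, so each downstream stage is testable as a
  recovery problem. Fully deterministic under a seed.
- **`chromatlas.state_selection`** — choosing the number of chromatin
  states from a family of emission models: best-match correlation against
  the richest model, and k-means cluster-separation (BetweenSS/TotalSS)
  over the pooled states, each with a fraction-of-maximum selection rule.
- **`chromatlas.states`** — replicate-consensus segmentation (sentinel
  `NRS` where replicates disagree), state coverage and between-sample
  variability, temporal state-transition graphs, and Ward clustering of
  samples on per-base state membership (binary/Jaccard distance).
- **`chromatlas.pcg`** — Polycomb-target classification of TSSs
  (active / repressed / unclassified by promoter-window state content) and
  genes, cumulative-fraction curves over tissue-stage counts, and 2x2
  fold-enrichment with chi-square.
- **`chromatlas.dtac`** — the accessible-region catalogue (merge replicated
  peak sets, per-sample membership, TSS-proximity), chromatin-state
  enrichment, sensitivity/specificity against reference sets, temporal
  dynamics between sequential stages (fold change >= 2, exact rate-ratio
  p <= 0.05), gain/loss state-transition enrichment, accessibility-vs-
  H3K27ac offset profiles, and TAD-constrained correlation maps with
  distance profiles and per-distance signed-rank tests.
- **`chromatlas.linking`** — candidate enhancer derivation (merge state-5
  calls, subtract TSS +/- 2.5 kb, pad to 2 kb), TAD-constrained
  enhancer-gene linking by Spearman correlation with a chromosome-wide
  empirical null (z-score and empirical p), replicate-map intersection, and
  evaluation against interaction and eQTL-style fixtures (mirrored control
  regions, distance-decile Fisher tests).
- **`chromatlas.dynamic_enhancers`** — dynamic 1-kb enhancer bins by
  moderated t with BH, unit-vector k-means clustering with a log-WSS elbow,
  motif enrichment against a signal-matched non-dynamic background, and
  super-enhancer calling by the stitched rank-signal slope-1 tangent
  cutoff.
- **`chromatlas.validation`** — validation-rate-vs-rank smoothing spline
  with the penalty solved for a target effective df (trace of the smoother
  matrix), background rates from missed elements, rank-sum combination of
  replicate rankings, cumulative positive curves and tier reports.

## CLI

The `chromatlas` entry point groups the main operations:

```sh
chromatlas simulate --seed 1 --outdir atlas/          # synthetic atlas + truth.json
chromatlas core merge in.bed out.bed
chromatlas core quantile-normalize matrix.tsv out.tsv
chromatlas select-states --models models/ --seed 0    # emissions_<k>.txt per rep dir
chromatlas pcg --annotation ann.tsv --consensus heart E11.5 cons.bed --out tss.tsv
chromatlas dtac build --peaks heart E11.5 peaks.bed --annotation ann.tsv --out cat.tsv
chromatlas dtac dynamics --counts atac.tsv --tissue heart --out dyn.tsv
chromatlas dtac correlate --signal atac_rpkm.tsv --tads tads.bed --out pairs.tsv
chromatlas link --enhancer-signal h3k.tsv --expression expr.tsv \
    --annotation ann.tsv --tads tads.bed --out map.tsv
chromatlas valrate --table validation.tsv --out curve.tsv
```

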