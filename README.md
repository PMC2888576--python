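# atexpand

Simulation and analysis pipeline for identifying adipose-tissue-expansion
(ATE) genes in a 3-nutrition-arm × 5-age factorial microarray design.

The package re-implements, as tested reusable components, the analysis
chain of a developmental-nutrition transcriptomics study:

1. **`atexpand.synth`** — a synthetic-data generator that emulates the
   study's structure: per-mouse adiposity phenotypes calibrated to the
   published group summary table (body weight / fat mass / lean mass /
   plasma leptin per arm and age), a persistent latent adiposity factor
   giving the published cross-age fat-mass correlations, pooled triplicate
   expression arrays for the 15 (arm × age) design cells, and planted gene
   classes (adiposity-tracking, diet-induced, under-nutrition-induced,
   developmental, maternal-diet, null) whose recoverability is known by
   construction.  A separate single-age cohort generator reproduces the
   litter-size / fat-mass / body-weight / adipocyte-area couplings.
2. **`atexpand.preprocess`** — quantile normalization across arrays and
   the three-criterion gene filter (minimum group signal 5000 in ≥3 of 15
   cells, ≥1.6-fold spread between extreme group means, two-tailed t-test
   P < 0.01 for ≥1 pairwise cell comparison), plus an optional
   Benjamini–Hochberg adjuster.
3. **`atexpand.clustering`** — row-standardized 15-cell profiles,
   K-means (k-means++ seeding, restarts, deterministic) and selection of
   the cluster whose centroid best matches a phenotype-derived template
   (fat-accumulation rate blended with marker-gene profiles).
4. **`atexpand.venn`** — five directional differential-expression sets
   (control vs under-nutrition at days 5 and 10; day 112 vs day 56 within
   each arm) and the intersection cascade F = A∩B, G = C∩D∩E,
   ATE = F∩G, with per-gene provenance.
5. **`atexpand.association`** — Pearson correlation with the
   t-transformation p-value, pairwise-complete correlation matrices with
   significance masks, percent relative cumulative frequency (PRCF)
   curves, variance explained, summary-statistic t-tests (pooled/Welch)
   and one-way ANOVA with a compact-letter display.
6. **`atexpand.io` / `atexpand.pipeline` / `atexpand.cli`** — plain-text
   I/O (CSV/TSV), a GEO series-matrix reader with a user-editable
   sample-title regex map, manifest-stamped outputs and the end-to-end
   driver.

## CLI

```sh
atexpand simulate phenotypes --seed 1 --out out/
atexpand simulate expression --seed 1 --out out/
atexpand simulate cohort3    --seed 1 --out out/
atexpand normalize --expression out/expression.tsv --design out/design.csv --out norm/
atexpand filter    --expression norm/expression_normalized.tsv --design norm/design.csv --out filt/
atexpand cluster   --expression norm/expression_normalized.tsv --design norm/design.csv -k 50 --out clust/
atexpand venn      --expression norm/expression_normalized.tsv --design norm/design.csv --out venn/
atexpand associate --phenotypes out/phenotypes.csv --out assoc/
atexpand run-all   --seed 1 --out run/            # full synthetic pipeline
```

`run-all` accepts a nested YAML config (`--config`) mirroring
`atexpand.pipeline.PipelineConfig`; every output directory carries a
`manifest.json` with the seed, package version and config hash, and reruns
are bit-identical.

## Notes on modelling choices

- Array noise is multiplicative lognormal (mean 1, configured CV);
  phenotypes are truncated normals per design cell.
- Plasma leptin is left-censored at a configurable detection floor;
  defaults leave roughly 5 of 24 under-nutrition pups quantifiable at day
  10.  The leptin and marker-gene couplings are calibrated by
  deterministic internal root-finding so that the pooled output
  correlations hit their configured targets.
- Null ("FLAT") genes carry small per-gene profile jitter below the fold
  threshold: they never survive the Venn cascade but keep the gene
  universe diverse enough for rank-based normalization and clustering to
  behave realistically.  Tiny gene universes (≲50 genes) degrade quantile
  normalization and are not recommended.
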