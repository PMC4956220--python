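# Methods

## The detection model

`locshift` compares two proteome-wide imaging screens — a wild-type and a
perturbation — at the level of per-gene feature profiles and asks, gene by
gene, whether the between-screen change of the profile is an outlier relative
to the changes of similar genes.

The core assumptions are:

1. **Changes are rare.** Only a small fraction of proteins relocalize under a
   perturbation, so the nearest neighbours of any gene in wild-type feature
   space are mostly static.
2. **Global effects are locally coherent.** Systematic between-screen shifts
   (illumination, focus, morphology) act similarly on genes that share a
   subcellular localization, i.e. that are close in feature space, but
   differently on different localization classes.
3. **Profiles are comparable between screens.** The same features, binning
   and aggregation are used for both screens, so subtracting profiles is
   meaningful.

Under these assumptions the change vectors of a gene's k nearest wild-type
neighbours estimate the local global effect, and the feature-wise modified
z-score of the gene's own change vector against them is a global-effect-
corrected outlier score. The median/MAD form keeps the score robust when a
few neighbours are themselves changed. Two exact properties follow from the
translation-equivariance and scale-equivariance of the median and MAD, and
are enforced by tests: adding a constant offset to the change vectors of a
query and all its neighbours leaves the z-scores unchanged (this is the
mechanism that cancels cluster-wide global effects), and scaling all change
vectors by a positive constant leaves them unchanged too.

The ranking statistic is the RMS of the z-scores over the 50 localization
features. Intensity columns still receive z-scores (they are informative for
interpretation) but are excluded from the RMS, because expression-level
changes are not localization changes.

## Pipeline parameters

| Parameter | Default | Meaning |
|---|---|---|
| `n_size_bins` | 5 | size bins per cell type (cell-cycle proxy) |
| `types_used` | bud, mother | lone cells dropped (`lone_policy="as_mother"` folds them in) |
| `min_cells` | 5 | per-bin floor in *both* screens for a gene to be retained |
| `aggregator` | mean | or `truncated_mean` (floor(0.05·n) cut per tail, per feature) or `median` |
| intensity divisor | 100 | rescales INT into the localization features' range |
| localization multiplier | 10 | rescales the five spread features |
| `k` | 50 | neighbours per gene; ties at the k-th distance broken by gene id |
| `z_cap` | 10 | cap on a z-score whose feature is fully degenerate (MAD and meanAD both 0) |

Size-bin boundaries default to per-type equal-frequency quintiles of the
*wild-type* size distribution, applied to both screens — quantile bins keep
per-bin sample sizes balanced, which is the reason for merging bins at all.
Explicit boundaries can be supplied (the synthetic generator publishes its
true bin edges and the benchmarks use them). Bins are half-open
`[lower, upper)` with the last bin closed above, so every size maps to
exactly one bin.

Numerical choices: the median of an even-sized neighbour set is the mean of
the two central order statistics (k = 50 exercises this constantly). When
`MAD_i = 0` the score falls back to the Iglewicz–Hoaglin form
`(x_i − x̃_i) / (1.2533 · meanAD_i)`; when the mean absolute deviation is also
zero, the score is 0 for a query exactly at the degenerate median and is
capped at ±`z_cap` otherwise, so a constant feature can never contribute an
infinity to the RMS. Neighbour search is exact (full pairwise distances);
RMS ties and distance ties are broken lexicographically by gene id, making
the whole pipeline deterministic.

The naive baseline column-standardizes the change matrix (sample SD, n−1)
and ranks by the same 50-feature RMS, so the two methods differ only in the
normalization; a flag switches the baseline to all 60 features.

## The synthetic screens

The generator emulates the data-generating structure the method assumes,
with all magnitude parameters expressed on the rescaled profile scale (the
scale on which distances and z-scores are computed):

- **Clusters.** `n_genes` = 1000 genes in `n_clusters` = 8 equal clusters
  (a `zipf` option skews sizes to exercise k exceeding a compartment's size).
  Cluster centres: intensity ~ U(2, 6), localization ~ U(5, 20); genes are
  centre + N(0, 0.5) — tight, well-separated localization classes.
- **Cells.** Cells per (gene, type, bin) ~ negative binomial (mean 12,
  dispersion 2) clamped at the filter floor of 5; cell features are the
  gene's per-bin profile + N(0, 1); sizes are drawn inside the intended bin.
- **Global effects.** Each cluster receives a shift with random direction
  and a norm from a geometric ladder 0.25–4× the change magnitude, randomly
  assigned to clusters. The ladder makes the unevenness of global effects —
  some localization classes hit dramatically, others barely — a structural
  property of every generated screen rather than a lottery of the seed.
  Its median matches the change magnitude, so raw change magnitude cannot
  separate real changes from global effects.
- **Changes.** 5% of genes receive a change: a random direction in the 50
  localization features (intensity untouched) with norm 0.3–1.7× the nominal
  `change_magnitude` of 4.5. Heterogeneous strengths matter: uniform strong
  changes would saturate recall and hide the k trade-off, whereas real
  changes range from dramatic relocalizations to subtle shifts in the
  proportion of cells per compartment. At these defaults the per-feature
  displacement of a typical change is below the single-cell noise, which
  places the benchmark in the informative regime (top-decile recall ~0.75–0.90
  rather than 1.0).
- **Outlier cells.** With probability `outlier_cell_rate` (default 0) a
  cell's features are replaced by profile + `outlier_scale`·N(0, 1) — the
  mis-segmented-cell failure mode that skews mean profiles. The benchmarks
  instead inject one targeted extreme cell (`inject_outlier_cell`, scale 500)
  into a known static gene, which reproduces the false-positive-under-mean /
  robust-under-median contrast directly.

All randomness flows from one master seed through per-stage substreams, so
enabling a later stage does not perturb earlier draws and fixed seeds give
byte-identical output tables.

**What the generator does not emulate:** real single-cell feature
distributions (heavy tails, feature correlations within cells), cell-cycle-
dependent localization trajectories across bins, segmentation artifacts
other than the injected outliers, correlated changes (multiple proteins
relocalizing identically, which the method is expected to miss), and
compartments that are intrinsically poorly separated by spread features.
Passing benchmarks therefore show that the implementation realizes the
method's intended behaviour under its own assumptions — not that the method
attains any particular recall on real screens.

## Benchmark problem sizes

The recovery benchmark uses three replicate 1000-gene screens; the k sweep
uses six replicate 800-gene screens (clusters of 100 genes, so k = 200
exceeds every compartment) because the k contrast is subtle — the method is
deliberately robust to k — and single replicates quantize recall in steps of
1/40. The global-effect contrast uses one 1000-gene screen with a single
shifted cluster and no true changes, scored by the shifted-cluster fraction
of the naive top decile and a chi-square uniformity test of the kNN top
decile's cluster composition.

## Known limitations

- Genes that change identically to their feature-space neighbours are
  invisible by construction (the local median absorbs a shared change).
- The MAD=0 fallback chain is ad hoc; it only matters for degenerate
  (constant) features, but the cap value trades off sensitivity against
  RMS domination by a single feature.
- Mean profiles are sensitive to single aberrant cells; median profiles
  trade that robustness against sensitivity to changes in the *proportion*
  of cells per compartment. Both are provided; the default follows the
  mean for interpretability of top hits.
- The evaluation drops known positives that did not survive filtering from
  the denominator; recall numbers are therefore conditional on the filtered
  gene set.
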