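# Methods

## Problem and model

`paddyfuse` maps rice planting structure — single-cropping rice, double-cropping
rice, regenerated (ratoon) rice, and other land cover — from a year of optical
satellite imagery. The per-pixel feature is the 12-month NDVI series obtained by
maximum-value compositing; the classifier is an ensemble of four standard
learners whose votes are fused with an accuracy-weighted scoring rule.

### NDVI and compositing

NDVI = (NIR − RED) / (NIR + RED), unitless in [−1, 1]. A pixel with
NIR + RED = 0 has no defined NDVI and becomes nodata (NaN), never an exception.
The monthly composite takes, per pixel and calendar month, the maximum NDVI over
all scenes acquired in that month, ignoring nodata — the standard maximum-value
composite that suppresses cloud contamination. Months are calendar months of
the acquisition date; a month with no valid observation is nodata, and pixels
whose required months are nodata are excluded from classification and counted
rather than guessed.

### Phenology decision-tree mask

Non-cropland is removed before machine learning with three sequential threshold
rules evaluated in fixed first-match order:

1. November NDVI > 0.4 → forest/meadow (perennial vegetation stays green after
   rice harvest);
2. otherwise, annual maximum NDVI < 0.1 → water;
3. otherwise, May–October maximum NDVI < 0.6 → built-up land / bare soil;
4. otherwise → candidate cropland.

First-match order resolves predicate overlap exactly as a decision tree would:
a constant-0.05 series satisfies both the water and built/bare predicates and
is labelled water because that rule is evaluated first. "Throughout the year"
means the maximum over the 12 composite values, "in November" the November
composite, "May to October" the maximum over those six months. Thresholds are
configuration values (`MaskThresholds`) so the mask ports to other regions; the
defaults above are the operational values for the Poyang Lake system.

### Base classifiers

Features are exactly the 12 monthly composite NDVI values in calendar order.
Four learners are trained on a 7:3 random train/validation split
(train size = ⌊0.7 N⌋; simple random, matching how the reference samples were
divided; a stratified option exists). Hyperparameters default to the tuned
operating points and are overridable:

| model | settings |
|---|---|
| KNN  | 7 neighbours, uniform weights, Minkowski p = 2, leaf size 50 |
| RF   | 500 trees, max depth 5, all features per split, random_state 1 |
| SVM  | RBF kernel, γ = 0.8, C = 0.95, one-vs-rest |
| GBDT | 500 stages, learning rate 0.1, max depth 3, random_state 1 |

KNN and SVM receive standardized features through a pipeline — distance and
kernel methods conventionally require it and the choice is documented here as
this package's decision; tree ensembles use raw NDVI. Hyperparameter search is
deliberately not re-run: the contribution under study is downstream of tuning.

### Scoring fusion

Each model's validation Overall Accuracy (percent) is its vote weight. Per
pixel, the weights of models voting the same class are summed into that class's
comprehensive score and the highest score wins. With accuracies 85/87/89/90 and
votes Type1/Type1/Type1/Type2, Type1 scores 85 + 87 + 89 + 0 = 261 against 90,
so Type1 wins. Properties verified exhaustively over all 256 four-model,
four-class vote patterns: scores sum to the weight total (conservation); a
common positive rescaling of the weights never changes a label, so percent vs
fraction weights is purely presentational; equal weights reduce the rule to
plurality voting; raising one model's weight can only move the label toward
that model's vote.

Tie-breaking (a genuinely open design point): ties on the comprehensive score
go to the class voted by the highest-weight individual model among the tied
classes, then to fixed model registration order (knn, rf, svm, gbdt). This is
deterministic, favours the empirically strongest model, and degenerates to
single-model behaviour when only one model is supplied. The fusion accepts any
number ≥ 1 of models. A per-class (user-accuracy-based) weight variant would be
an obvious extension but is not the specified mechanism and is not the default.

### Accuracy evaluation

With rows = actual and columns = predicted, `m_i` the diagonal, `G_i` row sums,
`C_i` column sums, `N` the total:

- OA = 100 · Σm_i / N
- Kappa = (N·Σm_i − Σ G_i C_i) / (N² − Σ G_i C_i); undefined (NaN) when the
  expected agreement is 1 (a single populated cell)
- Mapping (producer's) accuracy MA_i = 100 · m_i / G_i (NaN when G_i = 0)
- User accuracy UA_i = 100 · m_i / C_i (NaN when C_i = 0)

Improvements of the fused classifier over each base classifier are RELATIVE
percent changes, 100·(fused − base)/base, reported as a (min, max) range
rounded to 2 decimals; scalar metrics (OA, Kappa) compare one fused value
against each model, per-class metrics (UA, MA) pool the per-(model, class)
comparisons. Metrics are reported to 2 decimals; internal arithmetic is full
precision. Evaluation uses the labelled validation split only; masked
background classes are not pooled into the confusion matrices, though the
final map legend folds them into "other".

### Area, trend and driver analysis

Class areas are pixel counts × pixel area (default 0.01 ha, a 10 m grid cell).
Proportions are over total rice area by default (switchable to all classified
area). Time trends are ordinary least squares of value on year
(`scipy.stats.linregress`), requiring ≥ 3 years and non-constant years. Driver
relationships are Pearson r with two-sided t-test p-values
(`scipy.stats.pearsonr`), NaN for pairs with < 3 common years or zero
variance. No multiple-testing correction is applied; p-values carry stars at
0.05 / 0.01 / 0.001.

## Synthetic phenology generator

The generator emulates the qualitative NDVI phenology of the study system so
the full chain runs with no external data. Curves are Gaussian bumps on a
constant baseline (bump width 0.8 months), with a narrow negative bump forcing
the inter-crop trough; monthly values get i.i.d. Gaussian noise
(default sd 0.03) and are clipped to [−1, 1]. Noiseless default curves satisfy,
by construction and by test: double rice peaks in June and September with a
July trough; regenerated rice peaks in July and September with an August
trough; single rice one peak (mid-season sub-type month 8, late sub-type month
9, mixed equally within the class) then decline; all rice November NDVI < 0.3;
forest/meadow November > 0.5; water < 0.1 all year; built/bare < 0.25 all
year; an "other crop" class with a spring peak that survives the mask. All
amplitudes (rice peak 0.85, trough 0.45, baseline 0.15) are module defaults,
not measurements. Default class counts mirror the reference dataset:
2110 single / 1057 double / 522 regenerated / 1715 other = 5404 samples
(772 field-surveyed + 4632 interpreted).

What the generator does not emulate: mixed pixels, spatially correlated noise,
cloud-gap structure, inter-annual phenology shifts, and spectral confusion
between rice types. Synthetic classes are therefore nearly separable and all
four models approach 100% validation accuracy; passing tests demonstrate the
correctness and determinism of the pipeline machinery, not the real-data
accuracy level, which depends on the imagery and ground truth.

## Numerical and I/O choices

- Determinism: every random operation takes an explicit seed
  (`numpy.random.default_rng`); tree ensembles fix `random_state`; the
  train→predict→fuse chain is regression-tested to reproduce byte-for-byte.
- Rasters are plain multi-band TIFFs via `tifffile` (composite: 12 bands, band
  k = month k; masks and maps: uint8 with documented integer legends).
  Georeferencing tags are not interpreted; all operations are pixel-grid
  operations, and GeoJSON regions are rasterized by point-in-polygon tests at
  pixel centres in pixel coordinates.
- The end-to-end benchmark used by the test suite runs the full 5404-sample
  configuration (split 3782/1622) with all four models at their default
  hyperparameters; pipeline-level unit tests use reduced class counts and
  fewer trees to keep the suite fast, exercising identical code paths.

## Known limitations

- The synthetic benchmark cannot reproduce real-data accuracy figures; it
  verifies mechanism, invariants and arithmetic.
- The mask thresholds are fixed rules, not learned, and no morphological
  cleanup is applied.
- Fusion weights are one scalar (overall accuracy) per model; per-class
  weighting, probability averaging and stacking are out of scope.
- No atmospheric/geometric correction, reprojection or resampling: inputs are
  assumed co-registered analysis-ready NDVI (or band) rasters.
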