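# Methods

## Coordinate and timing conventions

All display coordinates are in pixels with the origin at the top-left
corner, x rightward, y downward; image-relative recordings must be
transformed to display coordinates before ingestion. Time is in seconds
from trial start; the CSV dialect may declare milliseconds and the reader
converts. Within a trial, fixations are kept sorted by onset with a
stable sort, so onset ties preserve file order.

## The spatiotemporal encoding

For a trial with fixations F ordered in time, an `EncodingConfig`
`(grid_x, grid_y, t)` defines `grid_x · grid_y` spatial cells tiling the
display exactly (cell width `display_w / grid_x`, height
`display_h / grid_y`; the centroid of cell (i, j) is
`((j + ½)·cell_w, (i + ½)·cell_h)`) and `t` temporal groups. Each group's
fixations are assigned to their nearest centroid and counted; the `t`
count grids are concatenated temporal-major with row-major cells, giving
a vector of fixed length `grid_x · grid_y · t`.

Deliberate conventions, each of which the tests pin down:

- **Temporal split.** Two modes. `time` (default): the span from the
  first onset to the last offset is cut into `t` equal half-open
  intervals `[a_k, a_{k+1})`, fixations assigned by onset, with the last
  interval closed on the right; this makes the encoding sensitive to
  trial duration (short trials leave later bins empty). `count`: the
  ordered fixations are dealt into `t` contiguous runs whose sizes differ
  by at most one, remainder to the front (`n = q·t + r` → the first `r`
  groups hold `q + 1`). A zero-span trial (all onsets equal, zero
  durations) puts every fixation into group 0.
- **Cell assignment.** Euclidean argmin over centroids. Because the
  centroids form an axis-aligned lattice, the argmin separates per axis
  and is computed that way; ties (points exactly on a cell boundary) go
  to the lowest row-major index. For points inside the display this is
  identical to index arithmetic `floor(x / cell_w)` except exactly on
  boundaries; the equivalence (including the boundary rule) is enforced
  by an exhaustive sweep plus fuzzing in the tests.
- **Off-display fixations.** Default `clamp`: the argmin naturally
  assigns them to the nearest edge cell, so the vector total equals the
  fixation count (count conservation). `drop` removes them before
  temporal grouping, for pipelines that pre-filter artifacts.
- **Grids.** Square by default (`grid_y = grid_x`), spanning the full
  display rectangle (not any image bounding box); rectangular grids are
  supported.

## Traditional baseline

Five per-trial attributes; area-of-interest features are excluded by
design because they require ground-truth abnormality annotations.

| attribute | definition | default parameters |
|---|---|---|
| total scan time | last offset − first onset (s) | — |
| fixation count | number of fixations | — |
| regressive fixation count | fixations returning to a previously visited location-grid cell after ≥1 intervening fixation in another cell (consecutive same-cell fixations are dwell) | 5×5 location grid |
| total saccade length | Σ Euclidean distance between consecutive fixations (px) | — |
| coverage | fraction of salient pixels within radius r of ≥1 fixation | r = 2% of the display diagonal (≈1° of visual angle on a desktop set-up) |

The revisit and coverage definitions are operationalisations: the
literature's "distinct locations revisited" and "percentage of salient
regions covered" do not fix a discretisation, so a configurable location
grid and fixation discs make them deterministic and testable. The
salient region of a grayscale image is the bounding box of the largest
connected component of the thresholded (default 0.05 after normalisation
to [0, 1]), morphologically closed foreground — the box is kept rather
than the thresholded set so dark structures inside the radiograph (lung
fields) stay salient while the peripheral black frame is excluded. An
all-black image raises a degenerate-mask error; with no image at all the
whole display counts as salient. "Saccade length" is spatial path
length, the standard reading, not inter-fixation time.

## Synthetic data generator

No raw clinical gaze data are available, so the generator produces
labelled two-class datasets with the statistical structure the analysis
assumes. Both classes draw fixations from a mixture of three components:

- a **systematic sweep** (probability `sweep_weight`): fixation targets
  progress left-to-right within top-to-bottom thirds of the display,
  emulating a trained raster-like search;
- **cluster visits**: a fixation lands near one of six fixed anchor
  positions (display fractions roughly covering two lung fields and the
  bases), drawn from per-cluster isotropic Gaussians;
- **revisits** (probability `revisit_prob` among cluster moves): the
  target cluster is re-drawn from those already visited in the trial.

Gaussian measurement jitter is added and coordinates are clamped into
the display. Durations are truncated-normal; onsets are cumulative
durations plus small saccade gaps.

A scalar `separation ∈ [0, 1]` interpolates every parameter linearly
between a common midpoint and the full class contrast: at 1, the faculty
archetype has a high sweep share (0.62), broad clusters (sd 0.13 of the
display) pushed outward, and few revisits (0.08), while the trainee
archetype concentrates 84% of its cluster mass on two tight clusters
(sd 0.032) with frequent revisits (0.55) and almost no sweep. At 0 the
archetypes are identical, so any classifier is at chance — and because
cluster anchors are fixed display fractions rather than per-participant
draws, there is no participant-identity signal to leak at separation 0
even in the two-participant preset. Fixation-count (negative binomial,
mean 42, dispersion 14) and duration (mean 0.26 s, sd 0.08 s) models are
shared by both classes at every separation, so the class signal is
carried by spatial and sequential structure, not by trivial scalar
summaries. On top of the archetype, each trial draws its own sweep share
and revisit probability (Beta around the archetype mean, concentration
5) and a log-normal cluster-spread factor (sd 0.3): real readers vary
from image to image, and this variability keeps the five classical
summaries overlapping between classes while the spatial layout remains
distinctive. The default `separation` is 0.8, at which the encoded
features separate the classes essentially perfectly — the regime the
method is designed for.

Presets mirror two acquisition styles: `eyelink_like` (detected
fixations; 1 participant per class × 55 trials = 110 trials; jitter sd
3 px) and `tobii_like` (raw ~33 Hz gaze treated as fixations, per the
substitution used with unprocessed gaze streams: ~320 samples per trial
with fixed 1/33 s inter-sample durations and 16 px jitter; 4 per class ×
27 trials = 216 trials). The default display is 1280×1024 px.
Reproducibility: one seed sequence per dataset is spawned into one
independent stream per trial, so datasets are bit-identical for a given
configuration and trials do not couple.

What the generator does **not** emulate: image-conditioned saliency,
main-sequence saccade dynamics, blinks and pupil behaviour,
participant-level idiosyncrasies within a class, or any quantitative
match to real readers' scan statistics (none are published for the
motivating studies). Passing benchmarks on this data therefore
demonstrate that the pipeline recovers a *planted* spatial/sequential
class contrast under realistic noise — not clinical performance.

## Benchmark protocol

- **Folds.** Stratified k-fold (default k = 10) with a fixed per-class
  hold-out (default 5): each class's indices are shuffled with the fold
  seed and dealt into k disjoint test chunks of 5 per class. With 55
  trials per class, 50 are dealt and 5 leftovers simply never appear in
  a test set (the description does not tile 110 evenly; this is
  documented, not hidden). Training is everything outside the fold's
  test set. Each CV seed regenerates the partition.
- **Feature extraction.** `none`, PCA, or RBF-kernel PCA; fitted on the
  training split only and applied to both splits (no test leakage).
  `dims` mode keeps a fixed component count (2 in the reference
  protocol); `variance` mode keeps the smallest count reaching a target
  cumulative (kernel-space, for KPCA) eigenvalue fraction (0.50 / 0.90 /
  0.99). The KPCA bandwidth uses the median pairwise training distance
  unless given explicitly.
- **Classifiers.** Gaussian process (RBF kernel, scale optimised on the
  marginal likelihood with the Laplace-approximated binary link; the
  length scale is *initialised* at the median pairwise training
  distance, since a unit start is a poor basin for unscaled count
  vectors), logistic regression, k-NN and XGBoost, the latter three
  tuned by an inner 3-fold stratified grid search maximising balanced
  accuracy (grids in `benchmark.DEFAULT_GRIDS`). Traditional features
  are standardised on training-fold statistics before classification;
  encoded counts are used raw by default (`standardize_encoded`
  switches this).
- **Metrics.** Trainee is the positive class. AUC is the rank statistic
  with ties counted ½ (verified against an all-pairs oracle in the
  tests); sensitivity is trainee recall, specificity faculty recall, F1
  on the trainee class. On a single-class test fold the AUC is
  undefined and recorded as NaN with a warning; the remaining metrics
  are still computed. Records are kept at the lowest level (device ×
  classifier × data type × feature extraction × grid × t × seed × fold)
  and all averages are taken directly over lowest-level records.
- **Selection and gains.** `select_best_config` maximises fold/seed-mean
  encoded AUC per classifier, ties broken toward the smaller grid, fewer
  temporal groups, and `fe=none`. `compare_gain` reports
  encoded-minus-traditional means per device and metric in percentage
  points.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the benchmark at a
reduced sweep — {5, 10} grids × {3, 10} temporal groups, GP and LR,
three CV seeds on one 110-trial dataset, plus a five-dataset
zero-separation control with LR — which is ample to establish the
directional result (best-config encoded AUC ≥ 0.9 and ≥ the traditional
baseline on identical folds; chance at separation 0) while keeping the
whole suite inside a coffee break. The full factorial ({5, 7, 10, 15} ×
{3, 5, 10, 20}, four classifiers, all feature-extraction variants)
remains the library default for real runs.

## Known limitations

- The AlexNet-style deep baseline of the surrounding literature is out
  of scope; any estimator with `fit`/`predict_proba` can be wired into
  `make_classifier` by extending the roster.
- The tensor (t-layer) representation for convolutional models is not
  implemented; the encoder emits flat vectors only.
- Fixation detection from raw samples (I-VT/I-DT), blink handling and
  native vendor formats are out of scope: ingestion expects delimited
  fixation tables.
- `compare_gain` averages over whatever records are present; comparing
  devices requires running the same sweep on each device's dataset.
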