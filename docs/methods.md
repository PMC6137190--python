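# Methods

## The recognition model

The package treats fish counting as moving-object recognition under a
single temporal assumption: in a time-sorted sequence of frames from a
fixed camera, the relevant subjects (fish) change position between
consecutive frames faster than the irrelevant content (seabed background,
illumination field, bio-fouling on the camera port). Consecutive-frame
absolute differencing therefore suppresses everything static and leaves
blobs where fish arrived or departed. Both signs of change are kept: a
moving fish produces a blob at its new position *and* a "ghost" at its old
one. Ghosts are not filtered geometrically — their image patch shows plain
background, so they fall to the classifier as natural negative examples.

Blob contours are deliberately summarised by their convex hulls: light
play on fish skin produces jagged, broken difference blobs, and the hull
recovers a stable region without requiring an accurate silhouette. RoIs
may overlap and no non-maximum suppression is applied; a school split into
several RoIs still contributes its magnitude to the count.

## Segmentation parameters

All configurable via `SegmentationParams`; defaults chosen as standard
small-object pipeline values and used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| k_blur / sigma_blur | 5 px / 1.5 | Gaussian pre-blur of the difference image |
| block_size | 51 px | window of the local Gaussian-weighted mean threshold |
| offset | 7 gray levels | foreground iff blurred diff > local mean + offset |
| k_morph | 5 px | elliptical structuring element (21-pixel ellipse), opening then closing |
| min_blob_area | 100 px | smallest component kept |

The local ("adaptive Gaussian") threshold was chosen over a global one:
illumination changes (dawn, dusk, artificial night light) shift the
difference image non-uniformly, and a local mean tracks that. One
consequence is documented in the tests: at the two photoperiod-transition
frames per day the whole illumination field changes, and the segmenter may
emit a few spurious regions there; their patches are plain background and
are rejected by the classifier.

Components whose pixels are exactly collinear cannot form a convex polygon
and are skipped; the morphological opening makes this unreachable at the
default kernel.

## Feature schema

23 named features: 9 texture (patch intensity mean, std, skewness,
kurtosis, histogram entropy; co-occurrence contrast, correlation, energy,
homogeneity at distance 1, averaged over the 0/45/90/135 degree offsets on
a 32-level quantisation) and 14 shape (hull area and perimeter,
circularity 4πA/P², bounding-box aspect ratio, solidity, extent,
best-fit-ellipse eccentricity, and the 7 Hu moment invariants log-scaled
as −sign(h)·log10|h|). Degenerate constant patches define skewness,
kurtosis, entropy, contrast and correlation as 0 and energy/homogeneity
as 1, so every vector is finite by contract.

The schema is a registry (`register_schema`) so an alternative feature list
can be swapped in without touching the learner — the GP performs its own
feature selection, so the method is robust to the exact feature superset.
Features are min-max normalized to [0, 1] with ranges learned on the
training pool and stored in the model; test-time values are clipped.

## The genetic-programming classifier

An individual is a prefix expression tree over terminals {normalized
features, ephemeral constants in [−1, 1]} and operators {+, −, ×,
protected ÷ (returns 1 on zero denominator), min, max, negation, 4-ary
if-greater}. A RoI is classified fish iff the tree value is positive.

Evolution is generational: ramped half-and-half initialisation (depths
2–6), tournament selection (size 5), subtree crossover (p = 0.8), subtree
or point mutation (p = 0.15), elitism 1, hard depth limit 8 (offspring
violating it are replaced by their first parent), population 200,
30 generations. Fitness is balanced accuracy minus a parsimony penalty
α·(tree size) with α = 0.001 — balanced accuracy rather than plain
accuracy so the fitness stays meaningful if a user changes the balanced
sampling; the parsimony term controls bloat and doubles as a soft feature
selector. All randomness flows from one `numpy` seed sequence, so
training is bit-reproducible.

Cross-validation follows the class-imbalance design of the training data:
candidate regions are overwhelmingly non-fish, so each of the (default 10)
repeats draws as many negatives as there are positives, without
replacement, reshuffles the positives, and splits both classes into 10
stratified folds. One tree is evolved per held-out fold; the fold
champion with the best held-out accuracy joins the ensemble, giving one
tree per repeat. The deployed classifier is the majority vote of these
champions with threshold θ = 0.5 on the vote fraction (the combiner is a
pluggable field of the model). The CV report carries per-fold confusion
counts and the mean ± std of ACC, TPR and FPR over all folds.

## Time-series evaluation

`build_series` pairs, per evaluable frame, the manual count with the
number of accepted RoIs. A frame is evaluable when it has an observed
count and a usable predecessor: the first frame of a sequence has no
difference image, and a frame whose predecessor is a transmission-error or
wrong-view frame has no valid difference either, so both are excluded
rather than scored against a meaningless difference image.

The "reduced" dataset drops wrong-camera-position and error frames (and
optionally observed counts above a crowding cutoff, disabled by default
because no principled cutoff exists). Aggregation scales: raw 30-min,
one mean per (calendar day, photoperiod), one mean per calendar month;
photoperiod comes from solar irradiance with a 5 W·m⁻² threshold
(configurable — the value separates any daylight reading from night
readings that are exactly 0 under artificial light). Correlations on
fewer than 3 pairs or against a constant series are reported as undefined
rather than 0.

## PERMANOVA

Univariate one-way PERMANOVA on Euclidean distances of square-root
transformed counts. The pseudo-F is computed from the distance-matrix
partition (total and within-group sums of squared pairwise distances
scaled by group sizes); in this univariate Euclidean case it equals the
classical one-way ANOVA F to machine precision, which the tests assert
against both `scipy.stats.f_oneway` and the independent PERMANOVA in
scikit-bio. The p-value uses free permutation of observations: all n!
relabelings are enumerated when n! ≤ n_perm (exact p), otherwise
Monte-Carlo with the (#{F* ≥ F} + 1)/(n_perm + 1) estimator
(default n_perm = 9,999). Pairwise contrasts report
pseudo-t = √(two-group pseudo-F); the full pair table is always returned
with a significance flag, leaving "report only significant pairs" to the
caller. The covariate autocorrelation filter greedily drops, from the
most correlated pair, the member with the larger mean |r| against the
remaining columns (ties break alphabetically), so the result is
independent of column order.

## The synthetic scene generator

The generator emulates, with exact ground truth, the conditions a fixed
observatory camera faces; its defaults are the study conditions used by
the test suite and the acceptance script:

- 240×320 frames every 30 min; static smooth background (level ~120) plus
  per-frame sensor noise (σ = 2 gray levels);
- fish as intensity-contrasted ellipses (semi-axes 9–16 × 5–8 px, contrast
  40–90 gray levels of either sign, mild texture noise), re-placed each
  frame at least one body length from their previous-frame positions;
  per-frame abundance Poisson with day mean 3.0 and night mean 1.0 (night
  abundance is genuinely lower at such sites); occasional schools
  (probability 0.05, Poisson-sized) of clustered, possibly overlapping
  bodies;
- turbidity score s → whole-frame Gaussian blur σ = 1.0·s plus contrast
  compression ×(1 − 0.15·s);
- fouling score s → 2·s static dark occluding patches (radius growing with
  s) drawn over the scene, with a fixed texture so they cancel exactly in
  differencing, growing by 1 px every 50 frames;
- night frames vignetted (artificial lighting falls off radially,
  strength 0.6); solar irradiance follows a diurnal sinusoid peaking at
  800 W·m⁻²;
- corrupted frames (pure noise, probability 0.02) and wrong-view frames
  (a different static scene, probability 0.01), flagged in the
  annotations with zero ground-truth count.

What it does *not* emulate: real fish morphology and articulation, optical
scattering physics, gradual turbidity drift within a sequence, fouling
translucency, and correlated fish revisits (each frame's placements are
independent). Passing tests therefore demonstrate that the pipeline's
operators interlock correctly and recover known dynamics under the stated
stressors — not field performance on any particular deployment, which
depends on contrast and size distributions of real fish.

Ground-truth labelling of training RoIs replaces manual annotation: a RoI
is positive iff its filled hull overlaps a true fish mask with IoU ≥ 0.3.
The threshold is deliberately permissive because partial-fish regions are
legitimate positives.

## Study conditions used by tests and the acceptance script

- Classifier training for end-to-end evaluation pools RoIs from six short
  sequences spanning (turbidity, fouling) = (0,0), (1,0), (2,1), (3,0),
  (0,2), (3,3) — a classifier deployed across a year must be trained
  across the conditions it will face, and training on clear water only
  and testing in turbid water measures domain shift, not the method.
- End-to-end evaluation uses 300-frame test sequences (about 6 days of
  simulated acquisition, ~290 evaluable frames after reduced-dataset
  filtering); learner-only checks use 400+400 (separable) and 200+200
  (null) example pools; the permutation-validity simulation uses 1,000
  null datasets of 16 observations at 199 permutations. These sizes give
  stable statistics while keeping a full run in the minutes range on one
  CPU.

## Known limitations

- Counting is RoI-level: one accepted region = one fish, so a school split
  into several regions over-counts individuals while preserving the
  abundance signal; dense overlap under-counts. The correlation analysis,
  not the absolute count, is the supported endpoint.
- The difference operator needs a valid predecessor; isolated frames and
  frames following corrupted ones are unusable by design.
- The classifier inherits the training pool's condition coverage; feature
  ranges outside the training min/max are clipped, which degrades, rather
  than breaks, extrapolation.
- PERMANOVA here is univariate only; multivariate resemblance matrices and
  dispersion tests are out of scope.
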