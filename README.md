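# fincount

Automated fish abundance recognition for fixed underwater time-lapse
cameras.

Cabled seafloor observatories image the same scene every 30 minutes, day
and night, for years. Turning those stills into an abundance time series by
eye is the bottleneck; `fincount` automates it under the conditions that
make underwater imagery hard — changing natural/artificial light, turbid
water, bio-fouling growing on the camera port, crowded fish schools, and
occasional corrupted or wrong-view frames.

## Method

The pipeline rests on one temporal assumption: fish change position between
consecutive frames faster than everything irrelevant (background,
illumination field, lens fouling) changes.

1. **Segmentation.** For consecutive frames I(t), I(t−1), compute the
   absolute difference |I(t) − I(t−1)|, Gaussian-blur it, threshold it
   against a local Gaussian-weighted mean (foreground iff the blurred
   difference exceeds the local mean by an offset c), and clean the binary
   mask with elliptical opening/closing. Each remaining connected
   component is summarised by the convex hull of its pixels; the hull's
   bounding box, mapped back onto the *original* frame, is a candidate
   region (RoI).
2. **Features.** Every RoI yields a 23-dimensional vector: 9 texture
   statistics (intensity mean/std/skewness/kurtosis/entropy and 4 gray-level
   co-occurrence properties averaged over four distance-1 offsets) and 14
   shape statistics (hull area/perimeter, circularity 4πA/P², bounding-box
   aspect, solidity, extent, ellipse eccentricity, 7 log-scaled Hu moment
   invariants). Features are min-max normalized with training-set ranges.
3. **Classifier.** A binary fish/non-fish decision function is *evolved*
   by genetic programming: expression trees over the normalized features
   with operators {+, −, ×, protected ÷, min, max, neg, if-greater}; a RoI
   is called fish when the tree evaluates positive. Training runs inside a
   repeated, class-balanced, stratified 10-fold cross-validation: each
   repeat draws as many negatives as there are positives (the raw RoI pool
   is dominated by non-fish regions), evolves one tree per held-out fold,
   and contributes its best tree to a majority-vote ensemble. Validation
   reports ACC = (TP+TN)/(TP+FP+FN+TN), TPR = TP/(TP+FN),
   FPR = FP/(FP+TN). Feature selection is implicit — features absent from
   the winning trees are unselected.
4. **Ecology.** Per-frame counts (number of RoIs the ensemble accepts)
   form the recognized abundance series, compared with manual counts by
   Pearson correlation at 30-min, day/night and monthly scales, stratified
   by turbidity and fouling score (0–3 each) and by dataset completeness
   (wrong-camera-position / transmission-error frames removed). Day-vs-night
   and month contrasts use univariate permutation PERMANOVA on the
   Euclidean resemblance of square-root transformed counts; an
   autocorrelation pre-filter (|r| < 0.70) screens environmental covariates.

Because real observatory imagery is available only on request, the package
ships a ground-truthed synthetic scene generator (`fincount.synthetic`)
that emulates every acquisition condition above, so the whole pipeline is
testable offline.

## Worked example

```sh
fincount simulate --out ds --seed 3 --n-frames 200
fincount train --dataset ds --out model.json --repeats 5 --seed 1
fincount predict --dataset ds --model model.json --out rec.csv --observed-out obs.csv
fincount evaluate --observed obs.csv --recognized rec.csv --out-prefix eval --n-perm 999
```

The same workflow from Python (see `examples/` for one script per
capability):

```python
from fincount import SceneConfig, generate_sequence, balanced_cv, build_series, \
    filter_reduced, pearson
from fincount.pipeline import build_pooled_examples

conditions = [(0, 0), (1, 0), (2, 1), (3, 0), (0, 2), (3, 3)]  # (turbidity, fouling)
datasets = [generate_sequence(SceneConfig(n_frames=60, turbidity=t, fouling=f,
                                          rng_seed=300 + i))
            for i, (t, f) in enumerate(conditions)]
pool = build_pooled_examples(datasets)
ensemble, report = balanced_cv(pool.X, pool.y, k=10, repeats=10, rng_seed=42)
print(report.summary())

seq, annotations, _ = generate_sequence(SceneConfig(n_frames=300, rng_seed=201))
observed, recognized = filter_reduced(*build_series(seq, annotations, ensemble))
print(pearson(observed, recognized))
```

On the reference synthetic conditions this prints a validation accuracy of
about 0.94 (std 0.02), true positive rate about 0.95 (std 0.03), false
positive rate about 0.07 (std 0.04), and a clear-water correlation between
true and recognized counts of r ≈ 0.95 (n ≈ 290, p ≪ 0.001): the evolved
classifier recovers the abundance dynamics almost exactly when the scene is
clean, and the correlation degrades gracefully as fouling occludes the
scene (r ≈ 0.83 at the heaviest fouling score) while high turbidity costs
only a few hundredths of r.

## Layout

- `src/fincount/io.py` — manifests, image loading, photoperiod labels,
  stratified frame sampling
- `src/fincount/segmentation.py` — differencing, thresholding, morphology,
  convex-hull RoIs
- `src/fincount/features.py` — texture/shape schema and normalization
- `src/fincount/gp.py` — the GP engine, balanced CV, the vote ensemble
- `src/fincount/timeseries.py` — paired series, stratification,
  aggregation, Pearson correlation
- `src/fincount/ecostats.py` — univariate PERMANOVA, pairwise contrasts,
  covariate autocorrelation filter
- `src/fincount/synthetic.py` — the ground-truthed scene generator
- `src/fincount/pipeline.py`, `src/fincount/cli.py` — workflow glue and the
  `fincount` command

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
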