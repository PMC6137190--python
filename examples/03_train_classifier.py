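"""Train the genetic-programming fish/non-fish classifier.

Builds an auto-labelled example pool from short sequences spanning several
turbidity/fouling conditions, runs the repeated balanced stratified 10-fold
cross-validation, and prints the validation metrics plus which features the
evolved trees actually use (implicit feature selection).

Takes a few minutes at the reference settings.
"""

from fincount import SceneConfig, balanced_cv, feature_usage, generate_sequence
from fincount.pipeline import build_pooled_examples

conditions = [(0, 0), (1, 0), (2, 1), (3, 0), (0, 2), (3, 3)]
datasets = [
    generate_sequence(SceneConfig(n_frames=40, turbidity=t, fouling=f, rng_seed=300 + i))
    for i, (t, f) in enumerate(conditions)
]
pool = build_pooled_examples(datasets)
print(f"example pool: {pool.n_positive} positive / {pool.n_negative} negative RoIs")

ensemble, report = balanced_cv(pool.X, pool.y, k=10, repeats=5, rng_seed=42)
s = report.summary()
print(f"validation ACC {s['acc_mean']:.2%} (std {s['acc_std']:.3f})")
print(f"validation TPR {s['tpr_mean']:.2%} (std {s['tpr_std']:.3f})")
print(f"validation FPR {s['fpr_mean']:.2%} (std {s['fpr_std']:.3f})")

used = {k: v for k, v in feature_usage(ensemble).items() if v > 0}
print("features used by the ensemble:", ", ".join(sorted(used)))
ensemble.to_json("model.json")
print("model written to model.json")
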