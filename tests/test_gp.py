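"""Expression-tree evaluation, fitness, evolution and balanced CV accounting."""

import numpy as np
import pytest

from fincount.features import MinMaxNormalizer
from fincount.gp import (
    GPClassifierEnsemble,
    GPConfig,
    balanced_accuracy,
    balanced_cv,
    classify_raw,
    confusion_rates,
    evaluate_individual,
    evaluate_tree,
    evolve,
    feature_usage,
    fitness,
    plan_balanced_folds,
    predict_count,
    random_tree,
    tree_depth,
    tree_from_prefix,
    tree_to_prefix,
)
from fincount.synthetic import generate_feature_dataset

NF = 23
FNAMES = [f"f{i}" for i in range(NF)]
FAST = GPConfig(population_size=50, generations=8)


def T(*tokens):
    return tree_from_prefix(list(tokens))


def test_simple_arithmetic_classification():
    # x3 - 0.5 on x3 = 0.7 -> raw 0.2 -> class 1
    tree = T("sub", "x3", 0.5)
    x = np.zeros(5)
    x[3] = 0.7
    assert evaluate_individual(tree, x) == 1
    x[3] = 0.2
    assert evaluate_individual(tree, x) == 0


def test_protected_division_returns_one_on_zero_denominator():
    tree = T("div", "x1", 0.0)
    x = np.array([0.0, 3.0])
    assert evaluate_tree(tree, x[None, :])[0] == 1.0
    assert evaluate_individual(tree, x) == 1


def test_output_always_binary_on_random_trees():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 6))
    for _ in range(50):
        tree = random_tree(6, GPConfig(), rng, max_depth=5, grow=True)
        out = classify_raw(tree, X)
        assert out.dtype == bool and out.shape == (20,)


def test_fitness_perfect_classifier_with_parsimony():
    # separating tree on a 10+10 balanced set, alpha * size subtracted
    X = np.zeros((20, 4))
    X[:10, 0] = 1.0
    y = np.array([1] * 10 + [0] * 10)
    tree = T("sub", "x0", 0.5)
    cfg = GPConfig(parsimony=0.001)
    assert fitness(tree, X, y, cfg) == pytest.approx(1.0 - 0.001 * len(tree))


def test_fitness_constant_one_tree_is_half():
    X = np.zeros((30, 2))
    y = np.array([1] * 15 + [0] * 15)
    tree = T(1.0)
    cfg = GPConfig(parsimony=0.0)
    assert fitness(tree, X, y, cfg) == pytest.approx(0.5)  # TPR 1, TNR 0


def test_fitness_invariant_to_example_order():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 5))
    y = rng.integers(0, 2, 40)
    y[:3] = 1
    y[3:6] = 0
    tree = T("add", "x2", "x4")
    perm = rng.permutation(40)
    cfg = GPConfig()
    assert fitness(tree, X, y, cfg) == pytest.approx(fitness(tree, X[perm], y[perm], cfg))


def test_evolve_separable_reaches_high_training_accuracy():
    X, y = generate_feature_dataset(100, 100, separation=5.0, rng_seed=4)
    Xn = MinMaxNormalizer().fit_transform(X)
    tree, _ = evolve(Xn, y, GPConfig(), rng_seed=11)
    assert balanced_accuracy(classify_raw(tree, Xn), y) >= 0.95


def test_evolve_deterministic_given_seed():
    X, y = generate_feature_dataset(30, 30, separation=2.0, rng_seed=5)
    Xn = MinMaxNormalizer().fit_transform(X)
    t1, f1 = evolve(Xn, y, FAST, rng_seed=3)
    t2, f2 = evolve(Xn, y, FAST, rng_seed=3)
    assert t1 == t2 and f1 == f2


def test_evolve_rejects_single_class():
    X = np.zeros((10, 3))
    with pytest.raises(ValueError):
        evolve(X, np.ones(10), FAST, rng_seed=0)


def test_depth_limit_respected_through_evolution():
    X, y = generate_feature_dataset(30, 30, separation=1.0, rng_seed=6)
    Xn = MinMaxNormalizer().fit_transform(X)
    cfg = GPConfig(population_size=40, generations=6, max_depth=4)
    tree, _ = evolve(Xn, y, cfg, rng_seed=9)
    assert tree_depth(tree) <= 4


def test_confusion_rate_identities():
    rng = np.random.default_rng(7)
    for _ in range(10):
        tp, fp, tn, fn = rng.integers(1, 50, 4)
        acc, tpr, fpr = confusion_rates(tp, fp, tn, fn)
        assert acc == pytest.approx((tp + tn) / (tp + fp + fn + tn))
        assert tpr == pytest.approx(tp / (tp + fn))
        assert fpr == pytest.approx(fp / (fp + tn))


def test_fold_plan_accounting():
    """Each repeat draws |positives| negatives; folds are disjoint,
    stratified (per-class sizes differ by <= 1) and exhaustive."""
    rng = np.random.default_rng(1)
    y = np.array([1] * 61 + [0] * 1000)
    plans = plan_balanced_folds(y, k=10, repeats=4, rng=rng)
    for sample, folds in plans:
        assert len(sample) == 2 * 61
        all_idx = np.concatenate(folds)
        assert len(np.unique(all_idx)) == len(all_idx)  # disjoint
        assert set(all_idx) == set(sample)  # exhaustive
        pos_sizes = [int((y[f] == 1).sum()) for f in folds]
        neg_sizes = [int((y[f] == 0).sum()) for f in folds]
        assert max(pos_sizes) - min(pos_sizes) <= 1
        assert max(neg_sizes) - min(neg_sizes) <= 1


def test_fold_plan_subsamples_positives_when_negatives_scarce():
    rng = np.random.default_rng(2)
    y = np.array([1] * 200 + [0] * 50)
    with pytest.warns(UserWarning):
        plans = plan_balanced_folds(y, k=10, repeats=1, rng=rng)
    sample, _ = plans[0]
    assert len(sample) == 100


def test_balanced_cv_deterministic_and_accounted():
    X, y = generate_feature_dataset(25, 80, separation=3.0, rng_seed=3)
    e1, r1 = balanced_cv(X, y, k=5, repeats=2, rng_seed=17, config=FAST,
                         feature_names=FNAMES)
    e2, r2 = balanced_cv(X, y, k=5, repeats=2, rng_seed=17, config=FAST,
                         feature_names=FNAMES)
    assert r1.folds.equals(r2.folds)
    assert [tree_to_prefix(t) for t in e1.individuals] == [
        tree_to_prefix(t) for t in e2.individuals
    ]
    sizes = r1.folds[["tp", "fp", "tn", "fn"]].sum(axis=1)
    assert (sizes == 10).all()  # 25+25 balanced sample over 5 folds
    assert len(e1.individuals) == 2


def _stub_ensemble(trees):
    norm = MinMaxNormalizer(minima=np.zeros(NF), maxima=np.ones(NF))
    return GPClassifierEnsemble(
        individuals=trees, feature_names=FNAMES, normalizer=norm
    )


def test_predict_count_contracts(clear_scene):
    from fincount.segmentation import segment_frame

    seq, _, _ = clear_scene
    rois = next(r for r in (segment_frame(seq, i) for i in range(1, 15)) if r)
    always_yes = _stub_ensemble([T(1.0)])
    always_no = _stub_ensemble([T(-1.0)])
    assert predict_count(always_yes, rois) == len(rois)
    assert predict_count(always_no, rois) == 0
    assert predict_count(always_yes, []) == 0
    split = _stub_ensemble([T(1.0), T(-1.0), T(-1.0)])  # 1/3 votes < theta
    assert predict_count(split, rois) == 0


def test_serialization_round_trip(tmp_path):
    X, y = generate_feature_dataset(25, 60, separation=3.0, rng_seed=8)
    ens, _ = balanced_cv(X, y, k=5, repeats=2, rng_seed=1, config=FAST)
    path = tmp_path / "model.json"
    ens.to_json(path)
    loaded = GPClassifierEnsemble.from_json(path)
    np.testing.assert_array_equal(ens.predict(X), loaded.predict(X))
    np.testing.assert_allclose(ens.normalizer.minima, loaded.normalizer.minima)


def test_schema_mismatch_rejected():
    ens = _stub_ensemble([T("x0")])
    with pytest.raises(ValueError, match="schema mismatch"):
        ens.predict(np.zeros((3, 5)))


def test_feature_usage_reports_fractions():
    ens = _stub_ensemble([T("add", "x0", "x1"), T("x0"), T(1.0)])
    usage = feature_usage(ens)
    assert usage["f0"] == pytest.approx(2 / 3)
    assert usage["f1"] == pytest.approx(1 / 3)
    assert usage["f5"] == 0.0
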