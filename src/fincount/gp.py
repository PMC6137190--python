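"""Genetic-programming binary classifier with balanced repeated stratified CV.

The recogniser is an evolved arithmetic expression tree over the normalized
RoI features; a RoI is called "fish" when the expression evaluates positive.
Training wraps the evolution inside a repeated, class-balanced, stratified
k-fold cross-validation: each repeat draws as many negatives as there are
positives (the raw RoI pool is heavily skewed towards non-fish regions),
forms stratified folds, evolves one tree per held-out fold and retains the
repeat's best tree.  The final classifier is the majority vote of the
per-repeat champions.

Feature selection is implicit: features that never appear in the winning
trees are unselected, and :func:`feature_usage` reports how often each
feature is used across the ensemble.

Expression trees are plain prefix token lists, evaluated vectorised over an
(n_examples, n_features) matrix, so no external GP framework is needed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, MinMaxNormalizer

# --- primitive set --------------------------------------------------------


def _pdiv(a, b):
    """Protected division: returns 1 wherever the denominator is zero."""
    b_arr = np.asarray(b, dtype=np.float64)
    safe = np.where(b_arr == 0.0, 1.0, b_arr)
    out = np.asarray(a, dtype=np.float64) / safe
    return np.where(b_arr == 0.0, 1.0, out)


def _ifgt(a, b, c, d):
    return np.where(np.asarray(a) > np.asarray(b), c, d)


PRIMITIVES: dict[str, tuple[int, callable]] = {
    "add": (2, np.add),
    "sub": (2, np.subtract),
    "mul": (2, np.multiply),
    "div": (2, _pdiv),
    "min": (2, np.minimum),
    "max": (2, np.maximum),
    "neg": (1, np.negative),
    "ifgt": (4, _ifgt),
}

_PRIM_NAMES = list(PRIMITIVES)

# A tree is a prefix list of nodes: ("op", name) | ("var", index) | ("const", value).
Tree = list[tuple]


@dataclass(frozen=True)
class GPConfig:
    """Evolution hyperparameters (reference defaults, all overridable)."""

    population_size: int = 200
    generations: int = 30
    tournament_size: int = 5
    p_crossover: float = 0.8
    p_mutation: float = 0.15
    elitism: int = 1
    max_depth: int = 8
    init_depth_min: int = 2
    init_depth_max: int = 6
    parsimony: float = 0.001
    const_low: float = -1.0
    const_high: float = 1.0


# --- tree utilities -------------------------------------------------------


def tree_depth(tree: Tree) -> int:
    depth = 0
    max_depth = 0
    pending = [1]  # children still expected at each open level
    for kind, payload in tree:
        max_depth = max(max_depth, depth)
        arity = PRIMITIVES[payload][0] if kind == "op" else 0
        if arity:
            pending.append(arity)
            depth += 1
        else:
            while pending and pending[-1] == 1:
                pending.pop()
                depth -= 1
            if pending:
                pending[-1] -= 1
    return max_depth


def subtree_span(tree: Tree, start: int) -> int:
    """End index (exclusive) of the subtree rooted at ``start``."""
    need = 1
    i = start
    while need:
        kind, payload = tree[i]
        need += (PRIMITIVES[payload][0] if kind == "op" else 0) - 1
        i += 1
    return i


def evaluate_tree(tree: Tree, X: np.ndarray) -> np.ndarray:
    """Vectorised evaluation over the rows of ``X``; returns (n,) floats."""
    pos = 0

    def rec():
        nonlocal pos
        kind, payload = tree[pos]
        pos += 1
        if kind == "var":
            return X[:, payload]
        if kind == "const":
            return payload
        arity, fn = PRIMITIVES[payload]
        args = [rec() for _ in range(arity)]
        with np.errstate(over="ignore", invalid="ignore"):
            out = fn(*args)
        return out

    out = rec()
    out = np.asarray(out, dtype=np.float64)
    if out.ndim == 0:
        out = np.full(X.shape[0], float(out))
    return np.nan_to_num(out, nan=0.0, posinf=1e12, neginf=-1e12)


def _random_terminal(n_features: int, config: GPConfig, rng: np.random.Generator):
    if rng.random() < 0.8:
        return ("var", int(rng.integers(n_features)))
    return ("const", float(rng.uniform(config.const_low, config.const_high)))


def random_tree(
    n_features: int,
    config: GPConfig,
    rng: np.random.Generator,
    max_depth: int,
    grow: bool,
) -> Tree:
    """Grow- or full-method random tree of depth at most ``max_depth``."""
    tree: Tree = []

    def build(depth: int) -> None:
        at_limit = depth >= max_depth
        if at_limit or (grow and rng.random() < 0.3 and depth >= 1):
            tree.append(_random_terminal(n_features, config, rng))
            return
        name = _PRIM_NAMES[int(rng.integers(len(_PRIM_NAMES)))]
        tree.append(("op", name))
        for _ in range(PRIMITIVES[name][0]):
            build(depth + 1)

    build(0)
    return tree


def tree_to_prefix(tree: Tree) -> list:
    """JSON-serialisable prefix token list, e.g. ["add", "x3", 0.5]."""
    out = []
    for kind, payload in tree:
        if kind == "op":
            out.append(payload)
        elif kind == "var":
            out.append(f"x{payload}")
        else:
            out.append(float(payload))
    return out


def tree_from_prefix(tokens: Sequence) -> Tree:
    tree: Tree = []
    for tok in tokens:
        if isinstance(tok, str) and tok in PRIMITIVES:
            tree.append(("op", tok))
        elif isinstance(tok, str) and tok.startswith("x"):
            tree.append(("var", int(tok[1:])))
        else:
            tree.append(("const", float(tok)))
    return tree


def tree_to_str(tree: Tree) -> str:
    """Human-readable nested form, e.g. ``add(x3, 0.5)``."""
    pos = 0

    def rec() -> str:
        nonlocal pos
        kind, payload = tree[pos]
        pos += 1
        if kind == "var":
            return f"x{payload}"
        if kind == "const":
            return f"{payload:.4g}"
        arity, _ = PRIMITIVES[payload]
        args = [rec() for _ in range(arity)]
        return f"{payload}({', '.join(args)})"

    return rec()


# --- fitness and evolution ------------------------------------------------


def classify_raw(tree: Tree, X: np.ndarray) -> np.ndarray:
    """Binary output of one individual: 1 iff the raw expression is > 0."""
    return evaluate_tree(tree, X) > 0.0


def evaluate_individual(tree: Tree, x: np.ndarray) -> int:
    """Classify a single normalized feature vector with one tree."""
    return int(classify_raw(tree, np.asarray(x, dtype=np.float64)[None, :])[0])


def balanced_accuracy(pred: np.ndarray, y: np.ndarray) -> float:
    pos = y == 1
    tpr = pred[pos].mean() if pos.any() else 0.0
    tnr = (~pred[~pos]).mean() if (~pos).any() else 0.0
    return 0.5 * (float(tpr) + float(tnr))


def fitness(tree: Tree, X: np.ndarray, y: np.ndarray, config: GPConfig) -> float:
    """Balanced accuracy minus a parsimony penalty on tree size."""
    pred = classify_raw(tree, X)
    return balanced_accuracy(pred, y) - config.parsimony * len(tree)


def _tournament(
    fits: np.ndarray, config: GPConfig, rng: np.random.Generator
) -> int:
    idx = rng.integers(len(fits), size=config.tournament_size)
    return int(idx[np.argmax(fits[idx])])


def _crossover(a: Tree, b: Tree, rng: np.random.Generator) -> Tree:
    i = int(rng.integers(len(a)))
    j = int(rng.integers(len(b)))
    return a[:i] + b[j : subtree_span(b, j)] + a[subtree_span(a, i) :]


def _mutate(
    tree: Tree, n_features: int, config: GPConfig, rng: np.random.Generator
) -> Tree:
    if rng.random() < 0.5:  # subtree replacement
        i = int(rng.integers(len(tree)))
        sub = random_tree(n_features, config, rng, max_depth=3, grow=True)
        return tree[:i] + sub + tree[subtree_span(tree, i) :]
    # point mutation: swap one node for a same-arity node
    i = int(rng.integers(len(tree)))
    kind, payload = tree[i]
    out = list(tree)
    if kind == "op":
        arity = PRIMITIVES[payload][0]
        choices = [n for n in _PRIM_NAMES if PRIMITIVES[n][0] == arity and n != payload]
        if choices:
            out[i] = ("op", choices[int(rng.integers(len(choices)))])
    else:
        out[i] = _random_terminal(n_features, config, rng)
    return out


def evolve(
    X: np.ndarray,
    y: np.ndarray,
    config: GPConfig | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[Tree, float]:
    """Evolve one classifier tree on a labeled, normalized training set.

    Generational GP with ramped half-and-half initialisation, tournament
    selection, subtree crossover, subtree/point mutation and elitism.
    Returns the best-of-run tree and its fitness; fully reproducible from
    the seed.  Requires both classes in ``y``.
    """
    config = config or GPConfig()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n_features = X.shape[1]

    # ramped half-and-half
    pop: list[Tree] = []
    depths = np.arange(config.init_depth_min, config.init_depth_max + 1)
    for i in range(config.population_size):
        d = int(depths[i % len(depths)])
        pop.append(random_tree(n_features, config, rng, max_depth=d, grow=i % 2 == 0))

    cache: dict[tuple, float] = {}

    def fit_of(t: Tree) -> float:
        key = tuple(t)
        if key not in cache:
            cache[key] = fitness(t, X, y, config)
        return cache[key]

    fits = np.array([fit_of(t) for t in pop])
    best_i = int(np.argmax(fits))
    best, best_fit = list(pop[best_i]), float(fits[best_i])

    for _ in range(config.generations):
        order = np.argsort(fits)[::-1]
        new_pop: list[Tree] = [list(pop[i]) for i in order[: config.elitism]]
        while len(new_pop) < config.population_size:
            r = rng.random()
            p1 = pop[_tournament(fits, config, rng)]
            if r < config.p_crossover:
                p2 = pop[_tournament(fits, config, rng)]
                child = _crossover(p1, p2, rng)
            elif r < config.p_crossover + config.p_mutation:
                child = _mutate(p1, X.shape[1], config, rng)
            else:
                child = list(p1)
            if tree_depth(child) > config.max_depth:
                child = list(p1)
            new_pop.append(child)
        pop = new_pop
        fits = np.array([fit_of(t) for t in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best, best_fit = list(pop[gen_best]), float(fits[gen_best])
    return best, best_fit


# --- cross-validation and the ensemble ------------------------------------


@dataclass
class CVReport:
    """Per-fold confusion counts and summary rates of a balanced CV run."""

    folds: pd.DataFrame  # columns: repeat, fold, tp, fp, tn, fn, acc, tpr, fpr

    def summary(self) -> dict[str, float]:
        s = {}
        for m in ("acc", "tpr", "fpr"):
            s[f"{m}_mean"] = float(self.folds[m].mean())
            s[f"{m}_std"] = float(self.folds[m].std(ddof=0))
        return s

    def to_csv(self, path: Path | str) -> None:
        self.folds.to_csv(path, index=False)

    def to_json(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def confusion_rates(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """ACC, TPR and FPR from confusion counts.

    ACC = (TP+TN)/(TP+FP+FN+TN), TPR = TP/(TP+FN), FPR = FP/(FP+TN).
    """
    acc = (tp + tn) / (tp + fp + fn + tn)
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    return acc, tpr, fpr


@dataclass
class GPClassifierEnsemble:
    """Majority vote over the per-repeat champion trees.

    ``vote_fraction`` is the share of trees voting "fish"; a RoI is counted
    as fish when that fraction exceeds ``theta``.  Normalization ranges are
    the training pool's per-feature min/max and travel with the model.
    """

    individuals: list[Tree]
    feature_names: list[str]
    normalizer: MinMaxNormalizer
    theta: float = 0.5
    rng_seed: Optional[int] = None
    combiner: str = "majority_vote"

    def vote_fraction(self, X_raw: np.ndarray) -> np.ndarray:
        if X_raw.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature schema mismatch: got {X_raw.shape[1]} features, "
                f"model expects {len(self.feature_names)}"
            )
        Xn = self.normalizer.transform(X_raw)
        votes = np.stack([classify_raw(t, Xn) for t in self.individuals])
        return votes.mean(axis=0)

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        return (self.vote_fraction(X_raw) > self.theta).astype(np.int64)

    def to_json(self, path: Path | str) -> None:
        payload = {
            "schema_version": 1,
            "feature_names": self.feature_names,
            "norm_min": self.normalizer.minima.tolist(),
            "norm_max": self.normalizer.maxima.tolist(),
            "theta": self.theta,
            "combiner": self.combiner,
            "rng_seed": self.rng_seed,
            "trees": [tree_to_prefix(t) for t in self.individuals],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: Path | str) -> "GPClassifierEnsemble":
        with open(path) as fh:
            payload = json.load(fh)
        norm = MinMaxNormalizer(
            minima=np.array(payload["norm_min"]), maxima=np.array(payload["norm_max"])
        )
        return cls(
            individuals=[tree_from_prefix(t) for t in payload["trees"]],
            feature_names=payload["feature_names"],
            normalizer=norm,
            theta=payload["theta"],
            rng_seed=payload.get("rng_seed"),
            combiner=payload.get("combiner", "majority_vote"),
        )


def feature_usage(ensemble: GPClassifierEnsemble) -> dict[str, float]:
    """Fraction of ensemble trees in which each feature appears."""
    n = len(ensemble.individuals)
    usage = {name: 0 for name in ensemble.feature_names}
    for tree in ensemble.individuals:
        present = {payload for kind, payload in tree if kind == "var"}
        for idx in present:
            usage[ensemble.feature_names[idx]] += 1
    return {k: v / n for k, v in usage.items()}


def plan_balanced_folds(
    y: np.ndarray, k: int, repeats: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, list[np.ndarray]]]:
    """Fold plan for repeated balanced stratified CV.

    Per repeat: draw as many negatives as positives (uniformly, without
    replacement) from the negative pool, reshuffle the positives, and split
    each class into ``k`` nearly equal chunks; fold ``j`` is the union of
    the j-th positive and negative chunks.  Returns, per repeat, the index
    array of the balanced sample and the list of per-fold index arrays
    (indices into the original pool).
    """
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) < k or len(neg) < k:
        raise ValueError(f"need at least k={k} examples of each class")
    n_take = len(pos)
    if len(neg) < len(pos):
        warnings.warn(
            "fewer negatives than positives: subsampling positives down",
            stacklevel=2,
        )
        n_take = len(neg)
    plans = []
    for _ in range(repeats):
        p = rng.permutation(pos)[:n_take]
        n = rng.permutation(neg)[:n_take]
        sample = np.concatenate([p, n])
        folds = [
            np.concatenate([pc, nc])
            for pc, nc in zip(np.array_split(p, k), np.array_split(n, k))
        ]
        plans.append((sample, folds))
    return plans


def balanced_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    repeats: int = 10,
    rng_seed: int = 0,
    config: GPConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> tuple[GPClassifierEnsemble, CVReport]:
    """Repeated balanced stratified k-fold CV; returns ensemble + report.

    ``X`` holds raw (unnormalized) features; min-max ranges are fitted on
    the full pool and stored with the model.  Each fold evolves a fresh
    tree on the k-1 training folds and is scored on the held-out fold; the
    best fold champion of each repeat (by held-out accuracy) joins the
    ensemble.  Deterministic given ``rng_seed``.
    """
    config = config or GPConfig()
    feature_names = list(feature_names or FEATURE_NAMES)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    norm = MinMaxNormalizer().fit(X)
    Xn = norm.transform(X)

    root_ss = np.random.SeedSequence(rng_seed)
    plan_rng = np.random.default_rng(root_ss.spawn(1)[0])
    plans = plan_balanced_folds(y, k, repeats, plan_rng)
    fold_seeds = root_ss.spawn(repeats * k)

    rows = []
    champions: list[Tree] = []
    for r, (sample, folds) in enumerate(plans):
        best_tree, best_acc = None, -1.0
        for j, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(sample, val_idx, assume_unique=False)
            rng = np.random.default_rng(fold_seeds[r * k + j])
            tree, _ = evolve(Xn[train_idx], y[train_idx], config, rng)
            pred = classify_raw(tree, Xn[val_idx])
            yv = y[val_idx]
            tp = int(np.sum(pred & (yv == 1)))
            fp = int(np.sum(pred & (yv == 0)))
            tn = int(np.sum(~pred & (yv == 0)))
            fn = int(np.sum(~pred & (yv == 1)))
            acc, tpr, fpr = confusion_rates(tp, fp, tn, fn)
            rows.append(
                dict(repeat=r, fold=j, tp=tp, fp=fp, tn=tn, fn=fn, acc=acc, tpr=tpr, fpr=fpr)
            )
            if acc > best_acc:
                best_tree, best_acc = tree, acc
        champions.append(best_tree)

    report = CVReport(folds=pd.DataFrame(rows))
    ensemble = GPClassifierEnsemble(
        individuals=champions,
        feature_names=feature_names,
        normalizer=norm,
        theta=0.5,
        rng_seed=rng_seed,
    )
    return ensemble, report


def predict_count(ensemble: GPClassifierEnsemble, rois: Sequence) -> int:
    """Number of RoIs the ensemble recognises as containing a fish."""
    from .features import feature_matrix

    if not rois:
        return 0
    X = feature_matrix(rois)
    return int(ensemble.predict(X).sum())
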