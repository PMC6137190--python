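"""Univariate permutation PERMANOVA and the covariate autocorrelation filter.

Abundance contrasts (day vs night, month vs month) are tested with a
permutational ANOVA on the Euclidean resemblance matrix of square-root
transformed counts.  In the univariate Euclidean case the pseudo-F computed
from the distance-matrix partition is algebraically identical to the
classical one-way ANOVA F; the p-value, however, comes from label
permutation rather than the F distribution, so no normality is assumed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PermanovaResult:
    pseudo_f: float
    df_between: int
    df_within: int
    p_perm: float
    n_permutations: int


def transform_abundance(values) -> np.ndarray:
    """Element-wise square root of non-negative abundance data."""
    v = np.asarray(values, dtype=np.float64)
    if (v < 0).any():
        raise ValueError("abundance values must be non-negative")
    return np.sqrt(v)


def _group_indices(groups) -> list[np.ndarray]:
    groups = np.asarray(groups)
    return [np.flatnonzero(groups == g) for g in pd.unique(groups)]


def _pseudo_f_from_d2(d2: np.ndarray, idx_groups: list[np.ndarray]) -> float:
    """Pseudo-F from the matrix of squared pairwise distances.

    SS_total = sum_{i<j} d2_ij / n ; SS_within = sum over groups of the
    within-group pairwise d2 divided by the group size; F is the usual
    among/within mean-square ratio.
    """
    n = d2.shape[0]
    g = len(idx_groups)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for idx in idx_groups:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    if ss_within <= 1e-300:
        return 0.0 if ss_among <= 1e-300 else np.inf
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def permanova_univariate(
    values,
    groups,
    n_perm: int = 9999,
    rng_seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on the Euclidean distances of univariate data.

    The null distribution uses free permutation of the observations.  When
    every relabelling can be enumerated (n! <= n_perm) the p-value is exact;
    otherwise it is the Monte-Carlo estimate (#{F_perm >= F_obs}+1) /
    (n_perm+1).  Deterministic given the seed.
    """
    x = np.asarray(values, dtype=np.float64)
    idx_groups = _group_indices(groups)
    if len(idx_groups) < 2:
        raise ValueError("need at least two groups")
    for idx in idx_groups:
        if len(idx) < 2:
            raise ValueError("every group needs at least two observations")
    n = len(x)
    g = len(idx_groups)
    d2 = (x[:, None] - x[None, :]) ** 2
    f_obs = _pseudo_f_from_d2(d2, idx_groups)

    sizes = [len(idx) for idx in idx_groups]
    bounds = np.cumsum([0] + sizes)

    def f_of_order(order: np.ndarray) -> float:
        perm_groups = [order[bounds[i] : bounds[i + 1]] for i in range(g)]
        return _pseudo_f_from_d2(d2, perm_groups)

    tol = 1e-12
    if n <= 9 and math.factorial(n) <= n_perm:
        total = 0
        ge = 0
        for order in itertools.permutations(range(n)):
            total += 1
            if f_of_order(np.asarray(order)) >= f_obs - tol:
                ge += 1
        p = ge / total
        n_used = total
    else:
        rng = np.random.default_rng(rng_seed)
        ge = 0
        for _ in range(n_perm):
            if f_of_order(rng.permutation(n)) >= f_obs - tol:
                ge += 1
        p = (ge + 1) / (n_perm + 1)
        n_used = n_perm
    return PermanovaResult(
        pseudo_f=float(f_obs),
        df_between=g - 1,
        df_within=n - g,
        p_perm=float(p),
        n_permutations=n_used,
    )


def pairwise_permanova(
    values,
    groups,
    n_perm: int = 9999,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All two-group contrasts with pseudo-t = sqrt(pseudo-F).

    Returns the full table (pair, t, p, significant-at-alpha); callers may
    filter on ``significant`` to report only the significant contrasts.
    """
    x = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    rows = []
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.spawn(len(labels) * (len(labels) - 1) // 2)
    k = 0
    for a, b in itertools.combinations(labels, 2):
        mask = (groups == a) | (groups == b)
        res = permanova_univariate(
            x[mask], groups[mask], n_perm=n_perm, rng_seed=int(seeds[k].generate_state(1)[0] % 2**31)
        )
        k += 1
        rows.append(
            dict(
                group_a=a,
                group_b=b,
                t=float(np.sqrt(res.pseudo_f)),
                p=res.p_perm,
                significant=res.p_perm < alpha,
            )
        )
    return pd.DataFrame(rows)


def autocorrelation_filter(covariates: pd.DataFrame, r_max: float = 0.70) -> list[str]:
    """Greedy removal of mutually correlated covariate columns.

    While any retained pair has |Pearson r| >= ``r_max``, the member of the
    most correlated pair with the larger mean |r| against the other retained
    columns is dropped; ties break towards dropping the alphabetically later
    name, so the result does not depend on column order.
    """
    if len(covariates) < 2:
        raise ValueError("need at least two complete rows")
    retained = sorted(covariates.columns)
    while len(retained) > 1:
        corr = covariates[retained].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.values.max()
        if worst < r_max:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = retained[i], retained[j]
        mean_a = corr.loc[a].drop(a).mean()
        mean_b = corr.loc[b].drop(b).mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        retained.remove(drop)
    return retained
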