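"""Inverse-odds weighting to a target population and balance diagnostics.

A propensity ``p`` of belonging to the target population is modeled by
main-effects logistic regression on the design matrix; the inverse-odds
weight ``w = p / (1 - p)`` standardizes the weighted group to the target
population's covariate distribution.  Balance is assessed by standardized
mean differences with the pooled SD computed on the unweighted sample, so
before/after comparisons share a denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

_EPS = 1e-6


class SeparationError(RuntimeError):
    """Perfect separation in the propensity model."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "perfect separation in propensity model; separating columns: "
            f"{self.columns}"
        )


def _find_separating_columns(X: np.ndarray, y: np.ndarray, names) -> list[str]:
    out = []
    for j, name in enumerate(names):
        a, b = X[y == 1, j], X[y == 0, j]
        if len(a) and len(b) and (a.min() > b.max() or b.min() > a.max()):
            out.append(name)
    return out


def fit_propensity(design_matrix, target_labels) -> np.ndarray:
    """Fitted probabilities of target-population membership, in (0, 1).

    Deterministic given the data (Newton solver on the unpenalized
    main-effects logistic likelihood, standardized internally).
    """
    X = np.asarray(design_matrix, dtype=float)
    y = np.asarray(target_labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("target labels must be binary")
    names = (list(design_matrix.columns)
             if isinstance(design_matrix, pd.DataFrame)
             else [f"x{j}" for j in range(X.shape[1])])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    model = LogisticRegression(C=1e8, solver="newton-cholesky", max_iter=200, tol=1e-9)
    model.fit(Xs, y)
    p = model.predict_proba(Xs)[:, 1]
    if p.min() < _EPS or p.max() > 1 - _EPS:
        cols = _find_separating_columns(X, y, names)
        raise SeparationError(cols or ["<no single separating column found>"])
    return p


def compute_weights(propensities, truncation_pct: float | None = None) -> np.ndarray:
    """Inverse-odds weights ``p / (1 - p)``; optional upper truncation at the
    given percentile (off by default)."""
    p = np.asarray(propensities, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("propensities must lie strictly in (0, 1)")
    w = p / (1.0 - p)
    if truncation_pct is not None:
        cap = np.percentile(w, truncation_pct)
        w = np.minimum(w, cap)
    return w


def weight_to_target(X_group: pd.DataFrame, X_target: pd.DataFrame,
                     truncation_pct: float | None = None) -> np.ndarray:
    """Inverse-odds weights standardizing ``X_group`` to the population that
    ``X_target`` samples.  Rows may overlap (a group can be part of its own
    target sample)."""
    X = pd.concat([X_target, X_group], axis=0, ignore_index=True)
    y = np.r_[np.ones(len(X_target)), np.zeros(len(X_group))]
    p = fit_propensity(X, y)
    return compute_weights(p[len(X_target):], truncation_pct)


def fit_group_membership(design_matrix, group_labels) -> pd.DataFrame:
    """Multinomial (softmax) model of group membership on the covariates.

    Returns a per-row probability DataFrame with one column per group.  This
    is the well-specified route to inverse-odds weights when the target
    population is a mixture of the sampled groups: a direct
    target-vs-group logistic has a softplus-shaped true log-odds that a
    main-effects model cannot represent, whereas pairwise group density
    ratios are plain linear indices.
    """
    X = np.asarray(design_matrix, dtype=float)
    labels = pd.Series(group_labels).reset_index(drop=True)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    try:
        model = LogisticRegression(C=1e8, solver="newton-cholesky",
                                   max_iter=200, tol=1e-9)
        model.fit((X - mu) / sd, labels)
    except Exception:  # singular Hessian etc.: fall back to quasi-Newton
        model = LogisticRegression(C=1e8, solver="lbfgs", max_iter=2000,
                                   tol=1e-8)
        model.fit((X - mu) / sd, labels)
    probs = model.predict_proba((X - mu) / sd)
    out = pd.DataFrame(probs, columns=model.classes_)
    # positivity check on each row's own class: a vanishing own-membership
    # probability means a diverging weight (separation); tiny probabilities
    # for *other* (e.g. rare) classes are expected and harmless
    own = probs[np.arange(len(out)), out.columns.get_indexer(labels)]
    if own.min() < _EPS:
        names = (list(design_matrix.columns)
                 if isinstance(design_matrix, pd.DataFrame)
                 else [f"x{j}" for j in range(X.shape[1])])
        worst = labels.iloc[int(np.argmin(own))]
        y = (labels == worst).to_numpy().astype(int)
        raise SeparationError(_find_separating_columns(X, y, names)
                              or [f"<no single separating column; class {worst!r}>"])
    return out


def mixture_target_weights(membership: pd.DataFrame, row_arms,
                           target_groups, truncation_pct: float | None = None,
                           arm_classes: dict | None = None) -> np.ndarray:
    """Inverse-odds weights toward the pooled target population.

    With target T = union of sampled groups, ``n_T f_T(x) = sum_{g in T}
    n_g f_g(x)``, so the stacked target-vs-arm odds equal
    ``sum_{g in T} P(g|x) / P(arm|x)`` — the exact inverse-odds weight
    ``p/(1-p)`` of target membership, computed without fitting the
    misspecified stacked regression.

    ``row_arms`` labels each row with the arm it belongs to in the analysis
    at hand; ``arm_classes`` maps an arm label to the membership-model
    classes composing it (default: the label itself), so that e.g. an arm
    pooling several care-setting classes uses ``P(arm|x) = sum_s P(s|x)``.
    """
    arms = pd.Series(row_arms).reset_index(drop=True)
    target_probs = membership[[g for g in target_groups
                               if g in membership.columns]].sum(axis=1)
    arm_classes = arm_classes or {}
    denom = np.empty(len(membership))
    for arm in arms.unique():
        cols = [c for c in arm_classes.get(arm, [arm])
                if c in membership.columns]
        denom[(arms == arm).to_numpy()] = membership[cols].sum(axis=1)[
            (arms == arm).to_numpy()]
    w = target_probs.to_numpy() / denom
    if truncation_pct is not None:
        w = np.minimum(w, np.percentile(w, truncation_pct))
    return w


def standardized_mean_difference(covariate, group_mask, weights=None) -> float:
    """(weighted mean_1 - weighted mean_0) / pooled SD, pooled SD unweighted:
    ``sqrt((s1^2 + s0^2) / 2)``.  Equal means with zero pooled SD give 0."""
    x = np.asarray(covariate, dtype=float)
    g = np.asarray(group_mask).astype(bool)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    m1 = np.average(x[g], weights=w[g])
    m0 = np.average(x[~g], weights=w[~g])
    s1 = x[g].std(ddof=1) if g.sum() > 1 else 0.0
    s0 = x[~g].std(ddof=1) if (~g).sum() > 1 else 0.0
    pooled = np.sqrt((s1 ** 2 + s0 ** 2) / 2.0)
    if pooled == 0:
        if np.isclose(m1, m0):
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    return float((m1 - m0) / pooled)


@dataclass
class BalanceReport:
    table: pd.DataFrame  # covariate, smd_before, smd_after

    @property
    def max_abs_smd_after(self) -> float:
        return float(self.table["smd_after"].abs().max())


def balance_report(X: pd.DataFrame, group_mask, weights) -> BalanceReport:
    """Per-covariate SMD before (unit weights) and after weighting."""
    rows = []
    g = np.asarray(group_mask).astype(bool)
    for col in X.columns:
        rows.append({
            "covariate": col,
            "smd_before": standardized_mean_difference(X[col], g),
            "smd_after": standardized_mean_difference(X[col], g, weights),
        })
    return BalanceReport(pd.DataFrame(rows))
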