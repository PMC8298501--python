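"""Interaction models, single-parameter epistasis, and variance statistics.

A multiplicative trait analysed on the raw (centimetre) scale shows up as
pairwise interactions between its predictors and as curvature in the
polygenic score: if ``height = A * 10**(s*sex + G + r*RP + eps)`` then a
first-order expansion yields products ``sex*G``, ``sex*RP``, ``G*RP`` and a
``G**2`` term, all of which vanish on the log scale.  This module fits

* the three-way interaction model
  ``y ~ sex + PGHS + RP + sex:PGHS + sex:RP + PGHS:RP`` (Wald tests per term),
* the collapsed epistasis model with a single coefficient ``beta2`` on the
  squared standardized polygenic score — valid when pairwise locus-locus
  interaction coefficients are proportional to products of the additive
  weights, so that dominance plus pairwise epistasis collapse onto PGHS²,
* Levene / Brown-Forsythe variance-heterogeneity tests, and
* ratio estimates with Fieller confidence intervals and delta-method SEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, SingularFitError
from .predictors import PredictorSet

__all__ = [
    "InteractionFit",
    "EpistasisFit",
    "RatioEstimate",
    "fit_interactions",
    "fit_epistasis",
    "variance_heterogeneity",
    "ratio_with_ci",
    "compare_ratios",
    "split_samples",
]


@dataclass
class InteractionFit:
    """OLS fit of the three-predictor model with all pairwise interactions."""

    table: pd.DataFrame  # index: term; columns: coef, se, t, p
    scale: str
    sample: str
    n: int

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "coef"])


@dataclass
class EpistasisFit:
    """Single-parameter epistasis fit: coefficient on the squared PGHS."""

    mu: float
    beta1: float
    beta2: float
    beta2_se: float
    beta2_p: float
    scale: str
    sample: str
    covariates: tuple[str, ...]
    table: pd.DataFrame
    n: int


@dataclass
class RatioEstimate:
    """A ratio of two estimates with a Fieller confidence set.

    ``unbounded`` flags the Fieller exclusive/unbounded case (denominator
    not significantly different from zero at the requested level), in which
    the reported bounds are infinite.
    """

    ratio: float
    ci_low: float
    ci_high: float
    method: str = "fieller"
    se_delta: float | None = None
    unbounded: bool = False


def _ols(y: np.ndarray, X: np.ndarray, names) -> pd.DataFrame:
    """Plain OLS with t-based Wald tests; returns a coefficient table."""
    n, k = X.shape
    if n <= k:
        raise SingularFitError("more parameters than observations")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise SingularFitError("singular design matrix") from exc
    cond = np.linalg.cond(XtX)
    if cond > 1e12:
        raise SingularFitError(f"near-singular design (condition number {cond:.2e})")
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - k)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - k)
    return pd.DataFrame({"coef": beta, "se": se, "t": t, "p": p}, index=list(names))


def _response(cohort: pd.DataFrame, scale: str) -> np.ndarray:
    h = cohort["height_cm"].to_numpy(float)
    if scale == "height":
        return h
    if scale == "logheight":
        return np.log10(h)
    raise DomainError("scale must be 'height' or 'logheight'")


def split_samples(cohort: pd.DataFrame, split_group=None) -> dict[str, np.ndarray]:
    """Boolean masks for ``all``, the reference group, and its complement.

    ``split_group=None`` uses the largest analysis group as reference
    (mirroring an "English" vs "all-but-English" replication split).
    """
    groups = cohort["group"]
    if split_group is None:
        split_group = groups.value_counts().idxmax()
    ref = (groups == split_group).to_numpy()
    return {
        "all": np.ones(len(cohort), dtype=bool),
        str(split_group): ref,
        f"all-but-{split_group}": ~ref,
    }


def _append_group_dummies(X, names, cohort, mask, adjust_group):
    """Add drop-first group dummies when the sample spans several groups."""
    if not adjust_group:
        return X, names
    glab = cohort["group"].to_numpy()[mask]
    levels = pd.unique(glab)
    if len(levels) < 2:
        return X, names
    dummies = [(glab == lv).astype(float) for lv in levels[1:]]
    X = np.column_stack([X, *dummies])
    names = list(names) + [f"group_{lv}" for lv in levels[1:]]
    return X, names


def fit_interactions(
    cohort: pd.DataFrame,
    predictors: PredictorSet,
    scale: str = "height",
    sample: str = "all",
    mask: np.ndarray | None = None,
    adjust_group: bool = True,
) -> InteractionFit:
    """Fit ``y ~ sex + PGHS + RP + sex:PGHS + sex:RP + PGHS:RP`` by OLS.

    All three pairwise interactions enter simultaneously; each term gets a
    two-sided Wald t-test against zero.  ``mask`` restricts the fit to a
    subsample (see :func:`split_samples`).  When the sample spans several
    analysis groups, group fixed effects are included by default
    (``adjust_group``): the predictors are standardized within groups, so
    leaving the between-group baseline differences in the residual would
    both inflate it and distort the Wald tests.
    """
    if mask is None:
        mask = np.ones(len(cohort), dtype=bool)
    y = _response(cohort, scale)[mask]
    sex = cohort["sex"].to_numpy(float)[mask]
    g = predictors.pghs[mask]
    r = predictors.rp[mask]
    X = np.column_stack([np.ones(y.size), sex, g, r, sex * g, sex * r, g * r])
    names = ["intercept", "sex", "pghs", "rp", "sex:pghs", "sex:rp", "pghs:rp"]
    X, names = _append_group_dummies(X, names, cohort, mask, adjust_group)
    return InteractionFit(table=_ols(y, X, names), scale=scale, sample=sample, n=int(y.size))


def fit_epistasis(
    cohort: pd.DataFrame,
    predictors: PredictorSet,
    scale: str = "height",
    adjust: tuple[str, ...] = ("sex", "rp"),
    sample: str = "all",
    mask: np.ndarray | None = None,
    standardized: bool = True,
    adjust_group: bool = True,
) -> EpistasisFit:
    """Fit the collapsed epistasis model ``y ~ PGHS + PGHS**2 (+ adjustments)``.

    ``beta2``, the coefficient on the squared polygenic score, absorbs
    dominance and pairwise epistatic curvature under the proportional-
    interactions assumption.  By default the standardized PGHS is squared
    without re-centring; ``standardized=False`` squares the raw weighted
    allele count instead (both variants are exposed because external
    conventions differ).  ``adjust`` names cohort/predictor columns to
    include as main effects alongside PGHS; multi-group samples get group
    fixed effects as in :func:`fit_interactions`.
    """
    if mask is None:
        mask = np.ones(len(cohort), dtype=bool)
    y = _response(cohort, scale)[mask]
    g = predictors.pghs[mask]
    if not standardized:
        # undo per-group standardization back to the raw score scale
        tab = predictors.standardization.set_index("group")
        glab = cohort["group"].to_numpy()[mask]
        g = g * tab.loc[glab, "sd"].to_numpy() + tab.loc[glab, "mean"].to_numpy()
    cols, names = [np.ones(y.size), g, g**2], ["intercept", "pghs", "pghs2"]
    for term in adjust:
        if term == "sex":
            cols.append(cohort["sex"].to_numpy(float)[mask])
        elif term == "rp":
            cols.append(predictors.rp[mask])
        elif term in cohort.columns:
            cols.append(cohort[term].to_numpy(float)[mask])
        else:
            raise DomainError(f"unknown adjustment term {term!r}")
        names.append(term)
    X = np.column_stack(cols)
    X, names = _append_group_dummies(X, names, cohort, mask, adjust_group)
    table = _ols(y, X, names)
    return EpistasisFit(
        mu=float(table.loc["intercept", "coef"]),
        beta1=float(table.loc["pghs", "coef"]),
        beta2=float(table.loc["pghs2", "coef"]),
        beta2_se=float(table.loc["pghs2", "se"]),
        beta2_p=float(table.loc["pghs2", "p"]),
        scale=scale,
        sample=sample,
        covariates=tuple(adjust),
        table=table,
        n=int(y.size),
    )


def variance_heterogeneity(values, groups, center: str = "median"):
    """Levene (mean-centred) or Brown-Forsythe (median-centred) test.

    One-way test of equal variances across the levels of ``groups`` based
    on absolute deviations from each group's centre; the median centre
    (default) is robust to non-normality.  Returns ``(statistic, p_value)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise DomainError("variance heterogeneity needs at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise DomainError("every group needs at least 2 values")
    stat, p = stats.levene(*samples, center=center)
    return float(stat), float(p)


def ratio_with_ci(
    num: float,
    num_se: float,
    den: float,
    den_se: float,
    cov: float = 0.0,
    alpha: float = 0.05,
) -> RatioEstimate:
    """Ratio of two (approximately) jointly normal estimates.

    The confidence set follows Fieller's theorem: the set of rho for which
    ``(num - rho*den)`` is not significantly different from zero, i.e. the
    solution of the quadratic inequality

        (den^2 - z^2 se_d^2) rho^2 - 2 (num*den - z^2 cov) rho
            + (num^2 - z^2 se_n^2) <= 0.

    When the denominator is not significantly nonzero at level ``alpha``
    the set is unbounded; the estimate is flagged and the bounds reported
    as infinite.  The delta-method SE
    ``|num/den| * sqrt(se_n^2/num^2 + se_d^2/den^2 - 2 cov/(num*den))``
    is attached for two-ratio comparisons.
    """
    if den == 0:
        raise DomainError("denominator estimate must be nonzero")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    a = den**2 - z**2 * den_se**2
    b = -2.0 * (num * den - z**2 * cov)
    c = num**2 - z**2 * num_se**2
    ratio = num / den
    # |r| * sqrt(se_n^2/num^2 + se_d^2/den^2 - 2 cov/(num den)) rewritten to
    # avoid dividing by a (possibly tiny) numerator
    inside = num_se**2 + ratio**2 * den_se**2 - 2.0 * ratio * cov
    se_delta = math.sqrt(max(inside, 0.0)) / abs(den)
    disc = b**2 - 4.0 * a * c
    if a <= 0:
        return RatioEstimate(
            ratio=ratio, ci_low=-math.inf, ci_high=math.inf,
            se_delta=se_delta, unbounded=True,
        )
    # a > 0: the point estimate always satisfies the inequality, so a
    # negative discriminant can only be rounding; the set degenerates to it
    root = math.sqrt(max(disc, 0.0))
    lo = (-b - root) / (2.0 * a)
    hi = (-b + root) / (2.0 * a)
    return RatioEstimate(ratio=ratio, ci_low=min(lo, hi), ci_high=max(lo, hi),
                         se_delta=se_delta)


def compare_ratios(r1: RatioEstimate, r2: RatioEstimate) -> tuple[float, float]:
    """Mean-difference z-test between two ratios using delta-method SEs.

    Returns ``(z, p)``; the two ratios are assumed independent.
    """
    if r1.se_delta is None or r2.se_delta is None:
        raise DomainError("both ratios need delta-method SEs")
    z = (r1.ratio - r2.ratio) / math.sqrt(r1.se_delta**2 + r2.se_delta**2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
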