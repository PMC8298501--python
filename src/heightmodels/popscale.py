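"""Cross-population scaling of height summary statistics.

Across world populations the standard deviation of adult height grows
roughly in proportion to the mean, while the coefficient of variation
(CV = SD / mean) stays flat, and mean male height is close to a constant
multiple (~1.08) of mean female height.  These are signatures of a
multiplicative (log-normal) trait rather than an additive (normal) one.
This module implements the summary-table stage of that analysis:

* quality filters for single-sex population tables (minimum sample size,
  exclusion of populations deviating by more than ``sd_mult`` cross-population
  SDs from the average),
* pairing and deduplication of male/female survey records,
* weighted least-squares fits of SD-on-mean, CV-on-mean and
  male-mean-on-female-mean, with the slope tested against an arbitrary
  null value (0 for scaling fits, 1 for the sex-ratio fit).

Population tables are plain :class:`pandas.DataFrame` objects; the expected
columns are documented on each function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConfigurationError, DomainError, SingularFitError

__all__ = [
    "FitResult",
    "weighted_linfit",
    "filter_single_sex_table",
    "pair_sexes",
    "scaling_report",
    "sex_ratio_fit",
]

#: columns required for a single-sex population summary table
SUMMARY_COLUMNS = ("population_id", "sex", "mean_height", "sd_height", "n")


@dataclass(frozen=True)
class FitResult:
    """Result of a (weighted) straight-line fit.

    Attributes
    ----------
    slope, intercept : float
        Coefficients of ``y = intercept + slope * x``.
    slope_se, intercept_se : float
        Standard errors of the coefficients.
    adj_r2 : float
        Weighted adjusted R²; the total sum of squares is taken about the
        weighted mean of the response.
    p_slope_vs : float
        Two-sided p-value of the t-test of ``(slope - null_value) / slope_se``
        with ``n - 2`` degrees of freedom.
    p_intercept : float
        Two-sided p-value of the intercept against zero.
    null_value : float
        The null slope the test was run against (0 for scaling fits,
        1 for the male-on-female sex-ratio fit).
    n_points : int
        Number of observations in the fit.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    adj_r2: float
    p_slope_vs: float
    p_intercept: float
    null_value: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "adj_r2": self.adj_r2,
            "p_slope_vs": self.p_slope_vs,
            "p_intercept": self.p_intercept,
            "null_value": self.null_value,
            "n_points": self.n_points,
        }


def weighted_linfit(x, y, w=None, null_slope: float = 0.0) -> FitResult:
    """Weighted least-squares fit of ``y`` on ``x``.

    Parameters
    ----------
    x, y : array-like
        Predictor and response, equal length >= 3.
    w : array-like, optional
        Non-negative regression weights; ``None`` or a constant vector
        reduces to ordinary least squares.  Only relative weights matter.
    null_slope : float
        Null value for the two-sided t-test on the slope.

    Raises
    ------
    SingularFitError
        If the weighted variance of ``x`` is zero.
    DomainError
        On length mismatch, fewer than 3 points, or invalid weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise DomainError(f"need at least 3 points, got {n}")
    if w is None:
        w = np.ones(n)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != x.shape:
            raise DomainError("weights must match x in length")
        if np.any(w < 0) or not np.any(w > 0):
            raise DomainError("weights must be non-negative and not all zero")

    xbar = np.average(x, weights=w)
    if np.average((x - xbar) ** 2, weights=w) <= 0:
        raise SingularFitError("zero weighted variance of x: cannot fit a slope")

    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    slope, intercept = res.params[1], res.params[0]
    slope_se, intercept_se = res.bse[1], res.bse[0]
    tstat = (slope - null_slope) / slope_se
    p_slope = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
    return FitResult(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        adj_r2=float(res.rsquared_adj),
        p_slope_vs=float(p_slope),
        p_intercept=float(res.pvalues[0]),
        null_value=float(null_slope),
        n_points=n,
    )


def filter_single_sex_table(
    records: pd.DataFrame, min_n: int = 1000, sd_mult: float = 3.0
) -> pd.DataFrame:
    """Quality-filter a single-sex population summary table.

    Two exclusions are applied in a single pass: populations with sample
    size below ``min_n`` are removed first, then populations whose mean
    height deviates from the cross-population average by more than
    ``sd_mult`` cross-population standard deviations.  Both the average
    and the SD are computed once, on the table remaining after the
    sample-size cut; statistics are not recomputed after exclusions.

    Parameters
    ----------
    records : DataFrame
        Columns ``population_id, mean_height, n`` at minimum; one row per
        population, all the same sex.
    min_n : int
        Minimum sample size to retain a population.
    sd_mult : float
        Outlier cut in cross-population SD units (``math.inf`` disables it).

    Returns
    -------
    DataFrame of surviving rows in input order.
    """
    if len(records) == 0:
        raise DomainError("empty population table")
    kept = records[records["n"] >= min_n]
    if len(kept) == 0:
        return kept
    mu = kept["mean_height"].mean()
    sd = kept["mean_height"].std(ddof=1)
    if not math.isfinite(sd_mult):
        return kept
    if sd == 0 or np.isnan(sd):
        return kept
    dev = (kept["mean_height"] - mu).abs()
    return kept[dev <= sd_mult * sd]


def pair_sexes(
    records: pd.DataFrame, sd_mult: float = 3.0
) -> pd.DataFrame:
    """Pair male and female survey records and deduplicate per population.

    The input is a long-format table with one row per population survey
    and sex: columns ``population_id, sex, mean_height`` plus the metadata
    the deduplication rules use (``country, ethnic_group, setting,
    age_low, age_high``).  ``sex`` is coded 0 = female, 1 = male;
    ``setting`` takes values such as ``general``, ``urban``, ``rural``.
    Rows sharing a ``population_id`` are the two sexes of one survey.

    Filtering proceeds in the stated order:

    1. surveys missing either sex (or with a missing mean) are dropped;
    2. surveys where either sex's mean deviates from that sex's average by
       more than ``sd_mult`` SDs are dropped (average and SD computed once
       over the complete pairs, single pass);
    3. one survey is retained per country/ethnic group, preferring
       ``general`` over urban/rural coverage, then the widest age interval,
       then the reference age closest to 21, then input order.  Ethnic
       groups within a country are treated as separate populations.

    Returns
    -------
    DataFrame with one row per retained population:
    ``population_id, country, ethnic_group, female_mean, male_mean`` plus
    the metadata columns.
    """
    needed = {"population_id", "sex", "mean_height", "country",
              "ethnic_group", "setting", "age_low", "age_high"}
    missing = needed - set(records.columns)
    if missing:
        raise ConfigurationError(f"pair_sexes: missing metadata columns {sorted(missing)}")

    meta_cols = ["country", "ethnic_group", "setting", "age_low", "age_high"]
    wide = (
        records.pivot_table(
            index="population_id", columns="sex", values="mean_height", aggfunc="first"
        )
        .rename(columns={0: "female_mean", 1: "male_mean"})
        .reset_index()
    )
    meta = records.drop_duplicates("population_id").set_index("population_id")[meta_cols]
    wide = wide.join(meta, on="population_id")
    # preserve input order of surveys
    order = {pid: i for i, pid in enumerate(records["population_id"].drop_duplicates())}
    wide["_order"] = wide["population_id"].map(order)
    wide = wide.sort_values("_order").reset_index(drop=True)

    # stage 1: drop incomplete pairs
    for col in ("female_mean", "male_mean"):
        if col not in wide.columns:
            wide[col] = np.nan
    complete = wide.dropna(subset=["female_mean", "male_mean"]).copy()

    # stage 2: per-sex >sd_mult SD screen; both sexes' statistics computed
    # once on the same complete-pair set (single pass)
    if math.isfinite(sd_mult):
        keep = np.ones(len(complete), dtype=bool)
        for col in ("female_mean", "male_mean"):
            mu = complete[col].mean()
            sd = complete[col].std(ddof=1)
            if sd > 0:
                keep &= ((complete[col] - mu).abs() <= sd_mult * sd).to_numpy()
        complete = complete[keep]

    # stage 3: deduplication per country/ethnic group
    complete = complete.copy()
    complete["_pref_setting"] = (complete["setting"] != "general").astype(int)
    complete["_neg_width"] = -(complete["age_high"] - complete["age_low"])
    complete["_age_dist"] = (complete["age_low"] - 21).abs()
    dedup = (
        complete.sort_values(
            ["_pref_setting", "_neg_width", "_age_dist", "_order"], kind="stable"
        )
        .drop_duplicates(["country", "ethnic_group"], keep="first")
        .sort_values("_order")
        .reset_index(drop=True)
    )
    return dedup.drop(columns=["_pref_setting", "_neg_width", "_age_dist", "_order"])


def scaling_report(records: pd.DataFrame) -> tuple[FitResult, FitResult]:
    """SD-on-mean and CV-on-mean regressions for a filtered single-sex table.

    Each population gets equal weight, so that a few very large surveys do
    not dominate the fit.  Both slopes are tested against zero.

    Returns ``(sd_fit, cv_fit)``.
    """
    mean = records["mean_height"].to_numpy(float)
    sd = records["sd_height"].to_numpy(float)
    sd_fit = weighted_linfit(mean, sd, None, null_slope=0.0)
    cv_fit = weighted_linfit(mean, sd / mean, None, null_slope=0.0)
    return sd_fit, cv_fit


def sex_ratio_fit(pairs: pd.DataFrame, null_slope: float = 1.0) -> FitResult:
    """Unweighted regression of mean male height on mean female height.

    A slope above 1 with an intercept near 0 indicates that male height is a
    constant *multiple* of female height (multiplicative sex effect); the
    slope is therefore tested against 1 by default.
    """
    return weighted_linfit(
        pairs["female_mean"].to_numpy(float),
        pairs["male_mean"].to_numpy(float),
        None,
        null_slope=null_slope,
    )
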