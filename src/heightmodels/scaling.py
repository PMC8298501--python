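"""Mean-variance and mean-effect scaling across cohort strata.

The diagnostic for a multiplicative trait: split the cohort into strata by
analysis group, sex, high/low polygenic score and high/low residual
predictor, then regress each stratum's SD (or each stratum's estimated
factor effect) on the stratum mean, with group-size weights.  Under a
log-normal trait the centimetre-scale slope is positive (SD and effects
scale with the mean, with slope roughly equal to the CV) while the
log-scale slope is zero; under an additive-normal trait both centimetre
slopes are flat.  Running the same machinery on both scales therefore
discriminates the generative scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .popscale import FitResult, weighted_linfit
from .predictors import PredictorSet

__all__ = ["stratify", "sd_vs_mean", "effect_vs_mean"]

FACTORS = ("sex", "pghs", "rp")


def _factor_columns(cohort: pd.DataFrame, predictors: PredictorSet) -> pd.DataFrame:
    """Assemble the three stratification factors as columns."""
    return pd.DataFrame(
        {
            "group": cohort["group"].to_numpy(),
            "sex": cohort["sex"].to_numpy(),
            "pghs": predictors.pghs,
            "rp": predictors.rp,
            "height_cm": cohort["height_cm"].to_numpy(float),
        }
    )


def stratify(
    cohort: pd.DataFrame, predictors: PredictorSet, factors=FACTORS
) -> pd.DataFrame:
    """Per-stratum summary statistics of height and log-height.

    Strata are all combinations of analysis group and the requested factors
    (a subset of ``sex``, ``pghs``, ``rp``).  Continuous factors are median
    split *within each analysis group*: ``high`` means strictly above the
    within-group median (values equal to the median go to the low half).
    With all three factors and six groups this yields the 48 = 6x2x2x2
    strata; with two factors, 24.

    Returns a DataFrame with one row per non-empty stratum: the stratum
    labels, ``n``, and mean/SD of height (cm) and of log10 height.
    Empty strata are dropped with a warning; single-individual strata have
    undefined SD and are likewise dropped.
    """
    bad = set(factors) - set(FACTORS)
    if bad:
        raise DomainError(f"unknown stratification factors: {sorted(bad)}")
    df = _factor_columns(cohort, predictors)
    keys = ["group"]
    for f in factors:
        if f == "sex":
            df["sex_high"] = df["sex"].astype(int)
            keys.append("sex_high")
        else:
            med = df.groupby("group")[f].transform("median")
            df[f"{f}_high"] = (df[f] > med).astype(int)
            keys.append(f"{f}_high")
    df["log10_height"] = np.log10(df["height_cm"])

    rows = []
    for key, sub in df.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        if len(sub) < 2:
            warnings.warn(f"stratum {dict(zip(keys, key))} has <2 individuals; dropped")
            continue
        rows.append(
            (
                *key,
                len(sub),
                sub["height_cm"].mean(),
                sub["height_cm"].std(ddof=1),
                sub["log10_height"].mean(),
                sub["log10_height"].std(ddof=1),
            )
        )
    return pd.DataFrame(rows, columns=[*keys, "n", "mean_h", "sd_h", "mean_logh", "sd_logh"])


def sd_vs_mean(
    strata: pd.DataFrame, scale: str = "height", weight_mult: float = 2.0
) -> FitResult:
    """Weighted regression of stratum SD on stratum mean.

    ``scale`` selects centimetre (``"height"``) or log10 (``"logheight"``)
    summaries.  Weights are ``weight_mult * n`` per stratum; slope
    estimates are invariant to ``weight_mult``, which only mirrors the
    conventions of the original figure captions (2n for the SD panels,
    n for the effect panels).
    """
    if scale == "height":
        x, y = strata["mean_h"], strata["sd_h"]
    elif scale == "logheight":
        x, y = strata["mean_logh"], strata["sd_logh"]
    else:
        raise DomainError("scale must be 'height' or 'logheight'")
    if len(strata) < 3:
        raise DomainError("need at least 3 strata")
    return weighted_linfit(
        x.to_numpy(float), y.to_numpy(float),
        weight_mult * strata["n"].to_numpy(float), null_slope=0.0,
    )


def _univariate_slope(y: np.ndarray, x: np.ndarray) -> float:
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        return np.nan
    return float(xc @ (y - y.mean())) / denom


def effect_vs_mean(
    cohort: pd.DataFrame,
    predictors: PredictorSet,
    factor: str,
    scale: str = "height",
    weight_mult: float = 1.0,
) -> tuple[pd.DataFrame, FitResult]:
    """Regress per-stratum factor effects on stratum means.

    The cohort is stratified by analysis group and the two factors *other*
    than ``factor`` (24 strata for six groups).  Within each stratum the
    effect of ``factor`` on height (or log-height) is the slope of a
    univariate OLS — the male-minus-female difference for sex, the change
    per 1 SD for the standardized scores.  These effects are then regressed
    on the stratum means with weights ``weight_mult * n``.

    Returns ``(strata_table, fit)``; the strata table carries the per-
    stratum effect estimates alongside the summary statistics.
    """
    if factor not in FACTORS:
        raise DomainError(f"factor must be one of {FACTORS}")
    others = tuple(f for f in FACTORS if f != factor)
    strata = stratify(cohort, predictors, factors=others)

    df = _factor_columns(cohort, predictors)
    for f in others:
        if f == "sex":
            df["sex_high"] = df["sex"].astype(int)
        else:
            med = df.groupby("group")[f].transform("median")
            df[f"{f}_high"] = (df[f] > med).astype(int)
    yname = "height_cm" if scale == "height" else "log10_height"
    if scale not in ("height", "logheight"):
        raise DomainError("scale must be 'height' or 'logheight'")
    df["log10_height"] = np.log10(df["height_cm"])

    keys = ["group"] + [f"{f}_high" for f in others]
    effects = {}
    for key, sub in df.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        effects[key] = _univariate_slope(
            sub[yname].to_numpy(float), sub[factor].to_numpy(float)
        )
    strata = strata.copy()
    strata["effect"] = [effects.get(tuple(r)) for r in strata[keys].itertuples(index=False)]
    strata = strata.dropna(subset=["effect"])
    xcol = "mean_h" if scale == "height" else "mean_logh"
    fit = weighted_linfit(
        strata[xcol].to_numpy(float),
        strata["effect"].to_numpy(float),
        weight_mult * strata["n"].to_numpy(float),
        null_slope=0.0,
    )
    return strata, fit
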