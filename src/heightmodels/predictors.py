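"""Cohort QC and the three height predictors: sex, polygenic score, residual.

The polygenic height score (PGHS) is the weighted count of height-increasing
alleles, ``sum_j a_j * g_ij``, built from an external additive weight table
and standardized (mean 0, variance 1) within each analysis group.  The
residual predictor (RP) collapses the sociodemographic and study covariates
into a single standardized score: a linear model of height on sex, PGHS and
the covariates is fitted, the fitted sex and PGHS contributions are
subtracted from the predicted height, and the remainder is standardized per
group.  Phenotype QC removes, within each group x sex stratum, individuals
deviating from the stratum mean by 4.75 SD or more — a cut calibrated so
that a cohort of several hundred thousand is expected to lose about one
individual per stratum under normality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError, SingularFitError

__all__ = [
    "PredictorSet",
    "qc_exclude_outliers",
    "filter_weight_table",
    "compute_pghs",
    "compute_residual_predictor",
    "standardize_by_group",
]


@dataclass
class PredictorSet:
    """Standardized predictors plus the design columns behind the RP.

    Attributes
    ----------
    pghs, rp : ndarray
        Standardized scores (mean 0, variance 1 within each analysis group).
    rp_components : DataFrame
        The fixed-effect design columns (covariates and dummy levels) that
        the RP collapses; used directly by the variance-explained models.
    standardization : DataFrame
        Per-group means and SDs applied, so scores are reproducible on new
        individuals.
    model_params : Series
        Coefficients of the underlying height model (for inspection).
    """

    pghs: np.ndarray
    rp: np.ndarray
    rp_components: pd.DataFrame
    standardization: pd.DataFrame
    model_params: pd.Series


def standardize_by_group(values, groups, ddof: int = 0):
    """Centre and scale ``values`` to mean 0 / variance 1 within each group.

    Returns ``(standardized, table)`` where ``table`` records the per-group
    mean and SD used.  A zero-SD group raises :class:`DomainError` (a
    constant score cannot be standardized).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    recs = []
    for g in pd.unique(groups):
        idx = groups == g
        mu = values[idx].mean()
        sd = values[idx].std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise DomainError(f"degenerate (constant) score in group {g!r}")
        out[idx] = (values[idx] - mu) / sd
        recs.append((g, mu, sd))
    table = pd.DataFrame(recs, columns=["group", "mean", "sd"])
    return out, table


def qc_exclude_outliers(cohort: pd.DataFrame, sd_cut: float = 4.75) -> pd.DataFrame:
    """Drop height outliers within each group x sex stratum.

    An individual is excluded when ``|height - stratum mean| >= sd_cut *
    stratum SD``; the stratum mean and SD are computed once on the full
    stratum (single pass).  Strata with fewer than 2 individuals, or with
    zero SD, are passed through unfiltered (with a warning for the former).
    """
    if not {"group", "sex", "height_cm"} <= set(cohort.columns):
        raise DomainError("cohort must have columns group, sex, height_cm")
    keep = np.ones(len(cohort), dtype=bool)
    h = cohort["height_cm"].to_numpy(float)
    for (g, s), idx in cohort.groupby(["group", "sex"]).indices.items():
        if len(idx) < 2:
            warnings.warn(f"stratum ({g}, {s}) has <2 individuals; not filtered")
            continue
        mu = h[idx].mean()
        sd = h[idx].std(ddof=1)
        if sd == 0:
            continue
        keep[idx] = np.abs(h[idx] - mu) < sd_cut * sd
    return cohort[keep]


_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


def filter_weight_table(
    weights: pd.DataFrame,
    locus_col: str = "locus_id",
    p_col: str = "p_value",
    thresholds: dict | None = None,
    drop_snps=(),
) -> pd.DataFrame:
    """Reduce a variant weight table to one well-behaved SNP per locus.

    Within each locus the SNP with the smallest ``p_col`` is kept (ties
    broken by lexicographic SNP id), after which configurable column
    thresholds are applied — e.g. ``{"p_value": ("<", 5e-10),
    "info": (">", 0.9), "eaf_diff": ("<", 0.05)}`` — and any SNP ids in
    ``drop_snps`` (e.g. ambiguous-allele variants) are removed.

    Raises :class:`ConfigurationError` if a threshold references a missing
    column.
    """
    thresholds = thresholds or {}
    for col in (locus_col, p_col):
        if col not in weights.columns:
            raise ConfigurationError(f"weight table lacks required column {col!r}")
    for col in thresholds:
        if col not in weights.columns:
            raise ConfigurationError(f"threshold references missing column {col!r}")

    out = weights[~weights["snp_id"].isin(set(drop_snps))]
    out = (
        out.sort_values([p_col, "snp_id"], kind="stable")
        .drop_duplicates(locus_col, keep="first")
    )
    for col, (op, value) in thresholds.items():
        if op not in _OPS:
            raise ConfigurationError(f"unknown threshold operator {op!r}")
        out = out[_OPS[op](out[col], value)]
    return out.sort_index()


def compute_pghs(
    genotypes: pd.DataFrame, weights: pd.DataFrame, groups
) -> tuple[np.ndarray, pd.DataFrame]:
    """Weighted count of height-increasing alleles, standardized per group.

    Rows of the weight table with negative weights are re-oriented so every
    effect allele increases height (dosage -> 2 - dosage, weight -> |weight|);
    the standardized score is invariant under such flips.  SNPs present in
    the weight table but absent from the genotype matrix are dropped with a
    warning.  The raw score ``sum_j a_j g_ij`` is centred and scaled to mean
    0 / variance 1 within each analysis group.

    Returns ``(scores, standardization_table)``.
    """
    present = weights["snp_id"].isin(genotypes.columns)
    if not present.all():
        missing = weights.loc[~present, "snp_id"].tolist()
        warnings.warn(f"{len(missing)} SNP(s) absent from genotypes, dropped: {missing[:5]}")
        weights = weights[present]
    if len(weights) == 0:
        raise DomainError("no weight-table SNPs present in the genotype matrix")
    w = weights["weight"].to_numpy(float)
    G = genotypes[weights["snp_id"]].to_numpy(float)
    flip = w < 0
    if flip.any():
        G = G.copy()
        G[:, flip] = 2.0 - G[:, flip]
        w = np.abs(w)
    raw = G @ w
    return standardize_by_group(raw, groups)


def _design_matrix(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariates as-is; categorical ones dummy-coded (drop-first)."""
    parts = []
    for col in covariates:
        s = cohort[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).rename(col))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    if not parts:
        raise DomainError("no covariate columns supplied for the residual predictor")
    return pd.concat(parts, axis=1)


def compute_residual_predictor(
    cohort: pd.DataFrame,
    pghs: np.ndarray,
    covariates=None,
    include_group: bool = True,
    orthogonalize: bool = True,
) -> PredictorSet:
    """Collapse sociodemographic covariates into one standardized predictor.

    A fixed-effects linear model of height on sex, PGHS, the covariate
    design columns and (optionally) analysis-group dummies is fitted by
    least squares.  The residual predictor is the fitted height minus the
    fitted sex and PGHS contributions; with ``orthogonalize=True`` (default)
    it is additionally residualized on ``[1, sex, PGHS]`` within each
    analysis group, so its sample correlation with sex and PGHS is zero by
    construction — exactly, both per group and overall, because the
    per-group standardization that follows is an affine map.  The result is
    standardized per analysis group.

    ``covariates=None`` uses every cohort column other than
    ``id, group, sex, height_cm``.

    Raises :class:`SingularFitError` on a rank-deficient design, naming the
    offending columns.
    """
    if covariates is None:
        covariates = [c for c in cohort.columns if c not in ("id", "group", "sex", "height_cm")]
    X_cov = _design_matrix(cohort, covariates)
    if include_group and cohort["group"].nunique() > 1:
        gdum = pd.get_dummies(cohort["group"], prefix="group", drop_first=True, dtype=float)
        X_cov = pd.concat([X_cov, gdum.set_axis(X_cov.index)], axis=1)

    sex = cohort["sex"].to_numpy(float)
    y = cohort["height_cm"].to_numpy(float)
    n = len(cohort)
    X = np.column_stack([np.ones(n), sex, np.asarray(pghs, float), X_cov.to_numpy(float)])
    names = ["intercept", "sex", "pghs", *X_cov.columns]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by pivoted QR diagonal
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise SingularFitError(f"rank-deficient design; suspect columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rp_raw = fitted - beta[1] * sex - np.asarray(pghs, float) * beta[2]
    if orthogonalize:
        glabels = cohort["group"].to_numpy()
        score = np.asarray(pghs, float)
        for g in pd.unique(glabels):
            idx = glabels == g
            Z = np.column_stack([np.ones(idx.sum()), sex[idx], score[idx]])
            gamma, *_ = np.linalg.lstsq(Z, rp_raw[idx], rcond=None)
            rp_raw[idx] = rp_raw[idx] - Z @ gamma
    if np.std(rp_raw) < 1e-10 * max(1.0, float(np.std(y))):
        raise DomainError(
            "residual predictor is (near-)constant: covariates explain no height "
            "variation beyond sex and PGHS"
        )
    rp, table = standardize_by_group(rp_raw, cohort["group"].to_numpy())
    return PredictorSet(
        pghs=np.asarray(pghs, float),
        rp=rp,
        rp_components=X_cov,
        standardization=table,
        model_params=pd.Series(beta, index=names),
    )
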