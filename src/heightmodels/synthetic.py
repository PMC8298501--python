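"""Synthetic cohorts and population tables with known generative truth.

Adult height in large cohorts behaves like a *multiplicative* trait: effects
of sex, polygenic score and environment multiply on the centimetre scale and
therefore add on the log scale, residuals are log-normal, and the SD scales
with the mean while the coefficient of variation (CV ~ 3-5%) stays flat.
Because individual-level biobank data are access-restricted, every
downstream stage of this package is exercised on synthetic cohorts drawn
from that generative model (or from its additive twin, for negative
controls):

    log10(height_i) = b[group_i] + s * sex_i + sum_j w_j * g_ij
                      + r * rp_i + eps_i,      eps_i ~ N(0, sigma^2)

with Hardy-Weinberg genotypes ``g_ij`` in {0, 1, 2}, a standard-normal
sociodemographic covariate ``rp`` and base-10 logs throughout, so a log-scale
effect ``s`` corresponds to a multiplicative factor ``10**s`` (the default
sex effect log10(1.08) makes men 8% taller).  Under ``scale="normal"`` the
same linear predictor is applied additively on the centimetre scale around
the group baselines, giving an additive-truth cohort with constant
centimetre effects and homoscedastic normal residuals.

The module also generates cross-population summary tables (mean, SD, n per
sex) with exact sampling noise, and "survey table" stand-ins that carry the
missing-sex rows, outliers and duplicate surveys the pairing filters are
designed to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = [
    "GenerativeConfig",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_population_summaries",
    "summaries_to_pairs",
    "simulate_worldwide_survey_table",
    "simulate_single_sex_table",
    "default_baselines",
]

LN10 = math.log(10.0)


def default_baselines(
    n_groups: int, center: float = math.log10(162.0), spread: float = 0.005
) -> np.ndarray:
    """Evenly spaced group baseline log-means, ``center +/- spread`` log10 units.

    The default spread of 0.005 log10 units (~1.9 cm around 162 cm) creates
    the modest between-group mean variation that the stratified
    SD-versus-mean analyses exploit.
    """
    if n_groups < 1:
        raise DomainError("n_groups must be >= 1")
    if n_groups == 1:
        return np.array([center])
    return center + np.linspace(-spread, spread, n_groups)


@dataclass
class GenerativeConfig:
    """Parameters of the synthetic cohort generator.

    Log-scale effect sizes are in log10 units: an effect ``e`` multiplies
    height by ``10**e``.  Defaults describe a biobank-like cohort: a 1.08
    male/female height ratio, a 100-SNP polygenic score contributing a
    log-scale SD of 0.010 (about a quarter of the within-stratum variance),
    a sociodemographic predictor contributing 0.007, and a residual
    log-scale SD of 0.017 — jointly a within-sex CV close to 4-5%.
    """

    n_individuals: int = 100_000
    n_groups: int = 6
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    baseline_log_mean: np.ndarray | None = None
    sex_log_effect: float = math.log10(1.08)
    snp_log_weights: np.ndarray | None = None
    genetic_log_sd: float = 0.010
    rp_log_effect: float = 0.007
    residual_log_sd: float = 0.017
    scale: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise DomainError("n_individuals must be >= 1")
        if self.n_groups < 1:
            raise DomainError("n_groups must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise DomainError("maf_range must lie within (0, 0.5]")
        if self.residual_log_sd <= 0:
            raise DomainError("residual_log_sd must be > 0")
        if self.scale not in ("lognormal", "normal"):
            raise DomainError("scale must be 'lognormal' or 'normal'")
        if self.baseline_log_mean is None:
            self.baseline_log_mean = default_baselines(self.n_groups)
        else:
            self.baseline_log_mean = np.asarray(self.baseline_log_mean, dtype=float)
            if self.baseline_log_mean.size != self.n_groups:
                raise DomainError("baseline_log_mean must have length n_groups")
        if self.snp_log_weights is not None:
            self.snp_log_weights = np.asarray(self.snp_log_weights, dtype=float)
            if self.snp_log_weights.size != self.n_snps:
                raise DomainError("snp_log_weights must have length n_snps")


@dataclass
class SyntheticCohort:
    """A generated cohort together with its generative truth.

    Attributes
    ----------
    cohort : DataFrame
        Columns ``id, group, sex, height_cm, rp``; sex coded 0 = female,
        1 = male; group labels 1..n_groups.
    genotypes : DataFrame
        Individuals x SNPs dosage matrix (0/1/2), columns are SNP ids.
    weights : DataFrame
        External-style additive weight table: ``snp_id, effect_allele,
        other_allele, weight, p_value, locus_id`` (weights in cm/allele).
    mafs : ndarray
        Allele frequencies used for the genotype draw.
    truth : GenerativeConfig
        The configuration that generated the data.
    """

    cohort: pd.DataFrame
    genotypes: pd.DataFrame
    weights: pd.DataFrame
    mafs: np.ndarray
    truth: GenerativeConfig


def simulate_genotypes(n: int, mafs, seed=0) -> np.ndarray:
    """Draw an ``n x len(mafs)`` dosage matrix under Hardy-Weinberg equilibrium.

    Column ``j`` is i.i.d. with genotype probabilities
    ``((1-p)^2, 2p(1-p), p^2)`` for ``p = mafs[j]``; equivalently
    ``Binomial(2, p)`` draws.  ``seed`` may be an integer or a
    ``numpy.random.Generator``.
    """
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    if n < 1:
        raise DomainError("n must be >= 1")
    if np.any(mafs <= 0) or np.any(mafs >= 1):
        raise DomainError("allele frequencies must lie strictly within (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int8)


def _assign_groups_sexes(n: int, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic group labels 1..n_groups and per-group balanced sexes."""
    groups = (np.arange(n) % n_groups) + 1
    sex = np.zeros(n, dtype=np.int8)
    # alternate sexes within each group
    for g in range(1, n_groups + 1):
        idx = np.flatnonzero(groups == g)
        sex[idx[1::2]] = 1
    return groups, sex


def simulate_cohort(config: GenerativeConfig) -> SyntheticCohort:
    """Generate a cohort under the configured multiplicative or additive truth.

    Under ``scale="lognormal"`` heights are ``10**(eta + eps)`` with the
    log-linear predictor ``eta`` described in the module docstring.  Under
    ``scale="normal"`` the same predictor (minus the group baseline) is
    converted once to centimetres with the grand-baseline factor
    ``10**mean(b) * ln(10)`` and added to the group baseline height, so the
    additive cohort carries constant centimetre effects and homoscedastic
    residuals — the mirror image used as a negative control.

    Output is byte-reproducible for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    if config.snp_log_weights is not None:
        w = config.snp_log_weights.copy()
    else:
        w = rng.normal(size=m)
        het = 2.0 * mafs * (1.0 - mafs)
        w *= config.genetic_log_sd / math.sqrt(float(np.sum(w**2 * het)))

    genotypes = simulate_genotypes(n, mafs, rng)
    groups, sex = _assign_groups_sexes(n, config.n_groups)
    rp = rng.normal(size=n)
    eps = rng.normal(scale=config.residual_log_sd, size=n)

    baseline = config.baseline_log_mean[groups - 1]
    gscore = genotypes @ w
    # centre the genetic score at its expectation so group baselines keep
    # their interpretation as group log-means
    gscore = gscore - float(np.sum(w * 2.0 * mafs))
    eta = config.sex_log_effect * sex + gscore + config.rp_log_effect * rp

    if config.scale == "lognormal":
        height = 10.0 ** (baseline + eta + eps)
    else:
        grand = 10.0 ** float(np.mean(config.baseline_log_mean))
        height = 10.0**baseline + grand * LN10 * (eta + eps)

    snp_ids = [f"rs{j + 1:05d}" for j in range(m)]
    cohort = pd.DataFrame(
        {
            "id": np.arange(n),
            "group": groups,
            "sex": sex,
            "height_cm": height,
            "rp": rp,
        }
    )
    geno_df = pd.DataFrame(genotypes, columns=snp_ids)
    mean_h = 10.0 ** float(np.mean(config.baseline_log_mean))
    weights = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": "A",
            "other_allele": "G",
            "weight": mean_h * LN10 * w,  # cm per allele, GWAS-style
            "p_value": 10.0 ** -rng.uniform(10, 60, size=m),
            "locus_id": [f"locus{j + 1:04d}" for j in range(m)],
        }
    )
    return SyntheticCohort(
        cohort=cohort, genotypes=geno_df, weights=weights, mafs=mafs, truth=config
    )


def simulate_population_summaries(
    n_pops: int,
    mean_range: tuple[float, float] = (150.0, 162.0),
    cv: float = 0.04,
    sex_ratio: float = 1.08,
    n_range: tuple[int, int] = (1000, 10000),
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-population summary table (both sexes) with exact sampling noise.

    Per population a true female mean is drawn uniformly in ``mean_range``
    and the true male mean is ``sex_ratio`` times it; true SDs are
    ``cv * mean``.  Observed means carry ``Normal(0, sd^2/n)`` noise and
    observed SDs follow the exact chi sampling distribution
    ``sd * sqrt(chi2(n-1)/(n-1))`` at the drawn sample size.

    Returns a long DataFrame with columns
    ``population_id, sex, mean_height, sd_height, n`` (sex 0 = female,
    1 = male), two rows per population.
    """
    if cv <= 0:
        raise DomainError("cv must be > 0")
    if sex_ratio <= 0:
        raise DomainError("sex_ratio must be > 0")
    if n_range[0] < 2:
        raise DomainError("n_range lower bound must be >= 2")
    cols = ["population_id", "sex", "mean_height", "sd_height", "n"]
    if n_pops == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pops):
        f_true = rng.uniform(*mean_range)
        for sex, mu in ((0, f_true), (1, sex_ratio * f_true)):
            sd_true = cv * mu
            n = int(rng.integers(n_range[0], n_range[1] + 1))
            mean_obs = mu + rng.normal() * sd_true / math.sqrt(n)
            sd_obs = sd_true * math.sqrt(rng.chisquare(n - 1) / (n - 1))
            rows.append((f"P{i + 1:04d}", sex, mean_obs, sd_obs, n))
    return pd.DataFrame(rows, columns=cols)


def summaries_to_pairs(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pivot a two-sex summary table into one row per population.

    Returns columns ``population_id, female_mean, male_mean``.  For tables
    carrying the survey metadata needed by the full deduplication rules use
    :func:`heightmodels.popscale.pair_sexes` instead.
    """
    wide = (
        summaries.pivot_table(
            index="population_id", columns="sex", values="mean_height", aggfunc="first"
        )
        .rename(columns={0: "female_mean", 1: "male_mean"})
        .reset_index()
    )
    return wide.dropna(subset=["female_mean", "male_mean"])


def simulate_worldwide_survey_table(
    n_pairs: int = 80,
    sex_ratio: float = 1.08,
    female_mean: float = 159.0,
    female_sd: float = 4.5,
    resid_sd: float = 1.1,
    n_missing: int = 6,
    n_outliers: int = 3,
    n_duplicates: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic stand-in for a worldwide male/female height survey table.

    Emulates the raw structure of compiled survey resources: ``n_pairs``
    clean country records (male mean = ``sex_ratio`` x female mean plus
    ``Normal(0, resid_sd^2)`` scatter), plus planted defects that the
    pairing pipeline is designed to remove — ``n_missing`` surveys with the
    male row absent, ``n_outliers`` countries displaced by +25 cm (beyond
    the 3-SD screen), and ``n_duplicates`` redundant surveys per the
    deduplication rules (urban coverage, narrower age interval, or a
    reference age farther from 21).  By construction
    :func:`heightmodels.popscale.pair_sexes` retains exactly ``n_pairs``
    populations.

    Female means are clipped at 2.6 SD so no legitimate record trips the
    outlier screen.  Output is the long format consumed by ``pair_sexes``.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    pid = 0

    def add_survey(country, f_mean, m_mean, setting="general",
                   age_low=21, age_high=49, ethnic_group="main"):
        nonlocal pid
        pid += 1
        base = dict(
            population_id=f"S{pid:04d}", country=country, ethnic_group=ethnic_group,
            setting=setting, age_low=age_low, age_high=age_high,
        )
        if f_mean is not None:
            rows.append({**base, "sex": 0, "mean_height": f_mean})
        if m_mean is not None:
            rows.append({**base, "sex": 1, "mean_height": m_mean})

    def draw_pair():
        # clipped draws guarantee clean surveys stay inside the 3-SD screen
        f = female_mean + np.clip(rng.normal() * female_sd, -2.6 * female_sd, 2.6 * female_sd)
        m = sex_ratio * f + np.clip(rng.normal() * resid_sd, -3.5 * resid_sd, 3.5 * resid_sd)
        return f, m

    dup_kinds = ["urban", "narrow_age", "far_age"]
    for i in range(n_pairs):
        country = f"C{i + 1:03d}"
        f, m = draw_pair()
        add_survey(country, f, m)
        if i < n_duplicates:
            kind = dup_kinds[i % len(dup_kinds)]
            f2, m2 = draw_pair()
            if kind == "urban":
                add_survey(country, f2, m2, setting="urban")
            elif kind == "narrow_age":
                add_survey(country, f2, m2, age_low=21, age_high=30)
            else:  # same width, reference age farther from 21
                add_survey(country, f2, m2, age_low=25, age_high=53)
    for i in range(n_missing):
        f, _ = draw_pair()
        add_survey(f"M{i + 1:03d}", f, None)
    # outliers sit at a fixed +25 cm displacement from the clean centre so
    # they exceed the 3-SD screen by construction even after inflating the
    # cross-population SD themselves
    for i in range(n_outliers):
        add_survey(f"O{i + 1:03d}", female_mean + 25.0,
                   sex_ratio * female_mean + 27.0)
    return pd.DataFrame(rows)


def simulate_single_sex_table(
    n_clean: int = 50,
    mean_range: tuple[float, float] = (150.0, 161.0),
    cv: float = 0.04,
    n_survey_range: tuple[int, int] = (1200, 8000),
    n_undersized: int = 1,
    n_outliers: int = 3,
    undersized_n: int = 800,
    outlier_shift: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic single-sex population table with planted filter targets.

    ``n_clean`` regular populations (mean uniform in ``mean_range``, SD =
    ``cv * mean`` with chi sampling noise), plus ``n_undersized``
    populations below the usual n >= 1000 cut and ``n_outliers``
    populations shifted by ``outlier_shift`` cm — far enough beyond the
    3-SD screen that :func:`heightmodels.popscale.filter_single_sex_table`
    retains exactly ``n_clean`` rows by construction.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(i, mu, n):
        sd_true = cv * mu
        sd_obs = sd_true * math.sqrt(rng.chisquare(n - 1) / (n - 1))
        mean_obs = mu + rng.normal() * sd_true / math.sqrt(n)
        rows.append((f"P{i:03d}", 0, mean_obs, sd_obs, n))

    k = 0
    for _ in range(n_clean):
        k += 1
        add(k, rng.uniform(*mean_range), int(rng.integers(*n_survey_range)))
    for _ in range(n_undersized):
        k += 1
        add(k, rng.uniform(*mean_range), undersized_n)
    # fixed displacement from the clean-range centre: guarantees the 3-SD
    # exclusion by construction at any seed despite the SD inflation the
    # outliers themselves cause
    centre = 0.5 * (mean_range[0] + mean_range[1])
    for _ in range(n_outliers):
        k += 1
        add(k, centre + outlier_shift, int(rng.integers(*n_survey_range)))
    return pd.DataFrame(
        rows, columns=["population_id", "sex", "mean_height", "sd_height", "n"]
    )
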