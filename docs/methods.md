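# Methods

## The question and the two models

Adult height is the textbook additive trait: effects of sex, polygenic
background and environment are conventionally summed in centimetres and the
residuals treated as normal.  The alternative is a multiplicative model, in
which the same effects act as factors on the centimetre scale and therefore
add on the logarithmic scale, residuals are log-normal, and both the
standard deviation and every effect size scale in proportion to the group
mean.  Throughout the package "log-height" means the base-10 logarithm of
height in centimetres, and all log-scale effect sizes are in log10 units
(an effect `e` multiplies height by `10**e`; the default sex effect
`log10(1.08)` makes men 8% taller).

Because the within-sex coefficient of variation of height is small (3-5%),
the two models are nearly indistinguishable at ordinary sample sizes.  The
package's pipeline is built around the places where they do separate:

1. **Cross-population scaling** (`popscale`): across populations, SD grows
   with the mean while CV stays flat, and mean male height is a constant
   multiple of mean female height (slope of the male-on-female regression
   tested against 1).
2. **Within-cohort stratified scaling** (`scaling`): strata defined by
   analysis group x sex x high/low polygenic score x high/low residual
   predictor (48 strata for six groups).  Under multiplicative truth the
   regression of stratum SD on stratum mean has slope ~CV on the cm scale
   and slope 0 on the log scale; per-stratum factor effects behave the same
   way.
3. **Interactions and collapsed epistasis** (`interactions`): a first-order
   expansion of `A * 10**(s*sex + G + r*RP + eps)` produces products
   `sex*G`, `sex*RP`, `G*RP` and a `G**2` term on the cm scale, all of which
   vanish on the log scale.  The `G**2` term is the collapsed epistasis
   model: a single coefficient beta2 on the squared standardized polygenic
   score, valid when pairwise locus-locus interaction coefficients are
   proportional to products of the additive weights.
4. **Model comparison** (`comparison`): variance explained by the same
   18-coefficient design fitted to height and to log-height (the log
   model's prediction exponentiated directly, no retransformation
   correction), out-of-group transferability, and tail/mid-distribution
   diagnostics.
5. **Null-genotype scan** (`nullsim`): type-I-error equivalence of the two
   scales for single-variant association tests.

## The synthetic cohort generator

Individual-level biobank data are access-restricted, so every stage is
exercised on synthetic cohorts with known generative truth:

    log10(height_i) = b[group_i] + s*sex_i + sum_j w_j g_ij + r*rp_i + eps_i

with Hardy-Weinberg genotypes (`Binomial(2, p_j)` dosages), a
standard-normal sociodemographic covariate `rp`, and
`eps ~ N(0, sigma^2)`.  Under `scale="normal"` the same linear predictor
(minus the group baseline) is converted once to centimetres with the
grand-baseline factor `10**mean(b) * ln(10)` and added to the group
baseline height: constant centimetre effects, homoscedastic normal
residuals — the additive negative control.

Defaults (chosen once, as a realistic biobank-like configuration):

| parameter          | default        | rationale |
|--------------------|----------------|-----------|
| `n_individuals`    | 100,000        | per-replicate size used in the discrimination study |
| `n_groups`         | 6              | number of analysis groups |
| `n_snps`           | 100            | order of a genome-wide significant height score |
| `maf_range`        | (0.05, 0.5)    | common variants |
| `sex_log_effect`   | log10(1.08)    | the ~8% male/female height ratio |
| `genetic_log_sd`   | 0.010 log10    | polygenic score explains ~25% of within-stratum log variance, the scale of modern height scores |
| `rp_log_effect`    | 0.007 log10    | sociodemographic predictor weaker than sex or genotype but strongly associated |
| `residual_log_sd`  | 0.017 log10    | residual CV ~3.9%; joint within-sex CV ~4.8%, inside the 3-5% band reported for adult height |
| baseline spread    | +-0.005 log10  | ~+-1.9 cm of between-group mean variation for the scaling fits to exploit |

SNP weights are drawn once per seed and rescaled so that
`sum_j w_j^2 * 2 p_j (1-p_j) = genetic_log_sd^2`.  The published-style
weight table is emitted in cm/allele (`mean_height * ln10 * w_j`);
standardization makes the score invariant to the unit choice.  The
generator is byte-reproducible for a fixed config and seed.

What the generator does *not* emulate: linkage disequilibrium between SNPs,
imputation dosages (hard calls only), assessment-centre/batch random
effects, multi-component sociodemographic structure (the residual predictor
is a single standard-normal covariate), and ascertainment. Passing tests
therefore show that the pipeline discriminates the generative scale under
clean conditions; they do not show robustness to LD, shared environment or
selection effects in real cohorts.

Two cross-population generators emulate summary-table inputs.
`simulate_population_summaries` draws true female means uniformly, sets
male means to `sex_ratio` times them and SDs to `cv * mean`, then adds
exact sampling noise (normal for the mean, chi for the SD, at the drawn
survey size).  `simulate_worldwide_survey_table` additionally plants the
defects the pairing filters must remove — surveys missing one sex,
countries displaced beyond the 3-SD screen, duplicate surveys (urban
coverage, narrower age interval, reference age farther from 21) — so the
filter pipeline retains a known number of populations by construction.
Its residual male-on-female scatter (1.1 cm) was calibrated a priori so a
~0.08 slope excess over 80 pairs is a ~3-SE effect, matching the study
conditions the worked example emulates.

## Predictors

**QC**: within each group x sex stratum, individuals deviating from the
stratum mean by >= 4.75 SD are excluded (single pass; a cut calibrated so a
cohort of several hundred thousand loses ~1 individual per stratum under
normality).  Zero-SD or <2-individual strata are passed through.

**PGHS**: one SNP per locus (lowest p, ties by SNP id), configurable
column thresholds, allele orientation flipped so every effect allele
increases height, weighted dosage sum, then centred and scaled to mean 0 /
variance 1 (population SD, ddof=0) within each analysis group.

**Residual predictor**: a fixed-effects linear model of height on sex,
PGHS, the covariate design columns and group dummies; RP = fitted height
minus the fitted sex and PGHS contributions, residualized on
`[1, sex, PGHS]` *within each analysis group*, then standardized per
group.  The within-group residualization is deliberate: it survives the
per-group affine standardization, so the RP's sample correlation with sex
and PGHS is exactly zero both per group and overall.  Centre/batch random
intercepts are approximated by fixed effects (dummy coding); a true mixed
model could be slotted in behind the same interface but is unnecessary for
any synthetic-data stage, and downstream analyses use only the composite
RP.

## Numerical and inferential choices

* **Weighted fits** use statsmodels WLS; the slope test is a two-sided t
  with n-2 df against a configurable null value (0 for scaling fits, 1 for
  the sex-ratio fit).  Adjusted R² is the weighted version with the total
  sum of squares about the weighted mean.  Uniform weights reduce exactly
  to OLS; slope estimates are invariant to overall weight scaling (which is
  why the 2n-vs-n weighting conventions of the SD and effect panels are
  preserved as parameters rather than harmonised).
* **Median splits**: "high" is strictly above the within-group median; ties
  go to the low half (ties are measure-zero for continuous scores).
* **Interaction/epistasis fits** use an in-package normal-equations OLS
  (checked against statsmodels in the tests) with t-based Wald tests.  When
  a sample spans several analysis groups, group fixed effects are included:
  the predictors are standardized within groups, so leaving the
  between-group baselines in the residual both inflates it and distorts the
  log-scale type-I error (simulations showed ~10-13% rejection without the
  adjustment, ~5% with it).  The squared PGHS is the square of the
  standardized score, not re-centred; squaring the raw weighted sum is
  available via `standardized=False`.
* **Fieller intervals** solve the quadratic
  `(den^2 - z^2 se_d^2) rho^2 - 2(num den - z^2 cov) rho + (num^2 - z^2 se_n^2) <= 0`
  with the normal critical value.  If the denominator is not significantly
  nonzero at the requested level the set is unbounded and flagged; with a
  significant denominator the point estimate always lies in the set, so a
  numerically negative discriminant collapses to a degenerate interval.
  Delta-method SEs back the two-ratio mean-difference z-test.
* **Back-transform convention**: variance explained subtracts
  `10**(predicted log-height)` with no retransformation correction — that
  is the convention being evaluated.  Because the r² here is var-based
  (invariant to additive constants), a *mean* correction such as Duan
  smearing need not improve it; the upper bound is the variance-optimal
  rescaling `cov(y, pred)/var(pred)`, exposed as `retransform="oracle"`
  alongside `"smearing"`.
* **Null scan**: Z = slope/SE of a univariate regression of the residual on
  each simulated genotype vector, computed via the correlation identity
  `Z = r sqrt((n-2)/(1-r^2))`; monomorphic draws are redrawn and counted.
  Default 10^4 simulations per allele frequency (the full-scale study used
  10^6; the CLI flag restores it).  Both scales see the same genotype draws
  by default, which maximizes the comparability of the two Z distributions.
  For identical residual inputs the two Z vectors coincide and the
  two-sample KS p-value is 1 (the test ignores the pairing).

## Transferability: what moves it and what does not

A pure between-group baseline shift is invisible to a model without a group
term — both the additive and the multiplicative model mispredict the level
identically, and which has the smaller median bias is noise.  The
multiplicative model's genuine transfer advantage appears when the target
group occupies a different region of the *predictor* distribution: its
log-linear form extrapolates the curvature correctly, while the additive
linearization accumulates bias (demonstrated in the tests by training on
the low polygenic-score tertile and predicting the high tertile).  Median
bias is `median(observed - predicted)` in centimetres, with log-model
predictions exponentiated first.

## Problem sizes

The replicated scale-discrimination study uses 200 cohorts of 100,000
individuals with the default configuration; machinery calibrations use
10^4 Fieller problems, 10^3 Levene replicates and 10^4 null-scan
simulations per allele frequency on a 20,000-individual cohort's
residuals.  These sizes put the raw-scale power of every diagnostic well
above one half while keeping a full run in minutes on one CPU; the CLI and
the acceptance script expose the sizes as flags.

## Known limitations

* The epistasis model is the collapsed single-parameter form only; no
  per-locus dominance coding or SNP x SNP scan.
* No LD, no imputation uncertainty, no mixed-model variance components.
* The cross-population generators emulate the *structure* of compiled
  survey tables, not any particular published compilation; worked-example
  statistics computed from them match published analyses in design
  (slope near 1.08 over 80 retained pairs) but not digit-for-digit.
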