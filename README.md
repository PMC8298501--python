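# heightmodels

Is adult height an **additive** trait (effects sum in centimetres, normal
residuals) or a **multiplicative** one (effects multiply, equivalently add
on the log scale, log-normal residuals)?  At the within-population
coefficient of variation of height (~3-5%) the two descriptions are nearly
indistinguishable — until sample sizes reach the hundreds of thousands, at
which point a multiplicative trait analysed on the centimetre scale betrays
itself through a characteristic syndrome: SD and effect sizes that scale
with the group mean, pairwise interactions between sex, polygenic score and
environment, apparent epistasis (a significant coefficient on the squared
polygenic score), and variance heterogeneity — all of which vanish when the
same data are analysed as log10(height).

`heightmodels` implements that entire diagnostic pipeline for
population-genetics and biostatistics researchers, together with a
synthetic-cohort generator so every stage is testable without
access-restricted biobank data.

## The core models

With `PGHS` the standardized polygenic height score (the weighted count of
height-increasing alleles, `sum_j a_j g_ij`, centred and scaled per
analysis group) and `RP` the standardized residual predictor
(sociodemographic covariates collapsed into one score orthogonal to sex
and PGHS), the package contrasts

    Height       = mu + b1*Sex + b2*PGHS + b3*RP + ... + eps
    log10 Height = mu + b1*Sex + b2*PGHS + b3*RP + ... + eps

through the interaction model (all pairwise products `Sex*PGHS`, `Sex*RP`,
`PGHS*RP` simultaneously, Wald tests), the collapsed epistasis model

    y = mu + beta1*PGHS + beta2*PGHS^2 + (sex, RP, group) + eps

whose single `beta2` absorbs dominance and pairwise epistasis when
interaction coefficients are proportional to products of additive weights,
stratified SD-vs-mean and effect-vs-mean regressions (48 = 6x2x2x2 strata
by group, sex, median polygenic score and median residual predictor),
cross-population regressions (SD and CV on mean; male mean on female mean,
slope tested against 1), variance explained by both models on the
centimetre scale, Levene/Brown-Forsythe variance-heterogeneity tests,
Fieller confidence intervals for effect ratios, and a Hardy-Weinberg
null-genotype type-I-error scan.

## Worked example

```python
import heightmodels as hm
from heightmodels.synthetic import simulate_worldwide_survey_table

# cross-population stage: pair sexes, filter, regress male on female mean
table = simulate_worldwide_survey_table(seed=0)   # survey-table stand-in
pairs = hm.pair_sexes(table)                      # 80 populations retained
fit = hm.sex_ratio_fit(pairs, null_slope=1.0)

# cohort stage: simulate, QC, build predictors, run the diagnostics
cfg = hm.GenerativeConfig(n_individuals=100_000, seed=1)   # multiplicative truth
sim = hm.simulate_cohort(cfg)
cohort = hm.qc_exclude_outliers(sim.cohort)
pghs, _ = hm.compute_pghs(sim.genotypes.loc[cohort.index], sim.weights,
                          cohort["group"].to_numpy())
pred = hm.compute_residual_predictor(cohort, pghs)
strata = hm.stratify(cohort, pred)                # the 48 strata
```

Output of the full diagnostic sweep on that cohort:

```
retained pairs: 80
slope  k = 1.106 +/- 0.028  (p vs 1: 0.0003)
intercept = -4.09 +/- 4.43  (p vs 0: 0.36)
SD-vs-mean [height   ]: k = +0.0415 +/- 0.0022  (p = 3.31e-23)
SD-vs-mean [logheight]: k = -0.0016 +/- 0.0022  (p = 4.60e-01)
sex:pghs   cm: +0.247 (p=3.4e-09)   log10: -1.50e-04 (p=0.16)
sex:rp     cm: +0.241 (p=8.2e-09)   log10: +6.71e-05 (p=0.53)
pghs:rp    cm: +0.034 (p=9.9e-02)   log10: -7.64e-05 (p=0.15)
beta2      cm: +0.046 (p=2.0e-03)   log10: +2.29e-06 (p=0.95)
r2 additive 0.6048  r2 multiplicative 0.6052  gain 0.035%
```

Reading it: the male-on-female slope of ~1.08-1.11 with an intercept near 0
says male height is a constant *multiple* of female height.  On the
centimetre scale the stratum SD rises by ~4 cm per 10 cm of mean (the CV),
the interactions are positive and the squared polygenic score is
significant; on the log scale every one of those signals disappears.  Yet
the multiplicative model explains only ~0.04% more height variance — the
scales differ in structure, not in fit.

## Command line

The `heightmodels` console script chains the stages from a shell:

```sh
heightmodels simulate --seed 1 --out-dir bundle/
heightmodels scaling  --bundle bundle/ --scale height
heightmodels interact --bundle bundle/ --scale logheight --split 1
heightmodels compare  --bundle bundle/ --train-group 1
heightmodels nullsim  --bundle bundle/ --n-sims 10000 --seed 1
heightmodels popscale --summaries summaries.tsv --pairs surveys.tsv
```

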