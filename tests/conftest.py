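import numpy as np
import pytest

import heightmodels as hm


def build_pipeline(config: hm.GenerativeConfig):
    """Generate a cohort and run QC + predictor construction."""
    sim = hm.simulate_cohort(config)
    cohort = hm.qc_exclude_outliers(sim.cohort)
    genotypes = sim.genotypes.loc[cohort.index]
    pghs, _ = hm.compute_pghs(genotypes, sim.weights, cohort["group"].to_numpy())
    predictors = hm.compute_residual_predictor(cohort, pghs)
    return sim, cohort, predictors


@pytest.fixture(scope="session")
def lognormal_pipeline():
    """Multiplicative-truth cohort (n=20k, 6 groups) with fitted predictors."""
    return build_pipeline(hm.GenerativeConfig(n_individuals=20_000, seed=42))


@pytest.fixture(scope="session")
def normal_pipeline():
    """Additive-truth cohort of the same size: the negative control."""
    return build_pipeline(
        hm.GenerativeConfig(n_individuals=20_000, seed=42, scale="normal")
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
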