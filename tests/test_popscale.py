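"""Population-table filters and the weighted-regression machinery."""

import math

import numpy as np
import pandas as pd
import pytest

import heightmodels as hm
from heightmodels.exceptions import ConfigurationError, DomainError, SingularFitError
from heightmodels.synthetic import simulate_single_sex_table, simulate_worldwide_survey_table


def brute_force_wls(x, y, w, null_slope=0.0):
    """Independent oracle: weighted normal equations solved directly."""
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    resid = y - X @ beta
    dof = len(x) - 2
    sigma2 = float(resid @ W @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ W @ X)
    return beta, np.sqrt(np.diag(cov))


class TestWeightedLinfit:
    def test_exact_line(self):
        fit = hm.weighted_linfit([0, 1, 2], [1, 3, 5], None)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = 2.0 + 0.5 * x + rng.normal(size=6)
        w = rng.uniform(0.1, 3.0, size=6)
        fit = hm.weighted_linfit(x, y, w)
        beta, se = brute_force_wls(x, y, w)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.slope == pytest.approx(beta[1], abs=1e-8)
        assert fit.slope_se == pytest.approx(se[1], rel=1e-8)

    def test_uniform_weights_reduce_to_ols(self, rng):
        x = rng.normal(size=20)
        y = 1 + x + rng.normal(size=20)
        a = hm.weighted_linfit(x, y, None)
        b = hm.weighted_linfit(x, y, np.full(20, 7.0))
        assert a.slope == pytest.approx(b.slope, abs=1e-12)
        assert a.slope_se == pytest.approx(b.slope_se, rel=1e-10)
        assert a.adj_r2 == pytest.approx(b.adj_r2, abs=1e-12)

    def test_null_slope_changes_only_p(self, rng):
        x = rng.normal(size=30)
        y = 1.1 * x + rng.normal(size=30) * 0.1
        f0 = hm.weighted_linfit(x, y, None, null_slope=0.0)
        f1 = hm.weighted_linfit(x, y, None, null_slope=1.0)
        assert f0.slope == f1.slope
        assert f0.p_slope_vs < f1.p_slope_vs  # slope near 1, far from 0

    def test_degenerate_x(self):
        with pytest.raises(SingularFitError):
            hm.weighted_linfit([1.0, 1.0, 1.0], [1, 2, 3], None)

    def test_too_few_points(self):
        with pytest.raises(DomainError):
            hm.weighted_linfit([0, 1], [0, 1], None)


class TestSingleSexFilter:
    def test_synthetic_54_to_50(self):
        """One undersized survey and three outliers planted in 54 records
        leave 50 after the n>=1000 and 3-SD screens."""
        table = simulate_single_sex_table(seed=0)
        kept = hm.filter_single_sex_table(table, min_n=1000, sd_mult=3.0)
        assert len(kept) == 50

    def test_identical_records_all_retained(self):
        df = pd.DataFrame(
            {"population_id": list("abc"), "mean_height": 160.0, "sd_height": 6.0,
             "n": 5000}
        )
        assert len(hm.filter_single_sex_table(df)) == 3

    def test_noop_filter(self):
        table = simulate_single_sex_table(seed=1)
        kept = hm.filter_single_sex_table(table, min_n=0, sd_mult=math.inf)
        pd.testing.assert_frame_equal(kept, table)

    def test_empty_raises(self):
        with pytest.raises(DomainError):
            hm.filter_single_sex_table(pd.DataFrame(columns=["mean_height", "n"]))


def _survey(pid, country, f, m, setting="general", age_low=21, age_high=49,
            ethnic_group="main"):
    rows = []
    for sex, v in ((0, f), (1, m)):
        if v is not None:
            rows.append(dict(population_id=pid, country=country,
                             ethnic_group=ethnic_group, setting=setting,
                             age_low=age_low, age_high=age_high,
                             sex=sex, mean_height=v))
    return rows


class TestPairSexes:
    def test_synthetic_table_retains_80(self):
        table = simulate_worldwide_survey_table(seed=0)
        pairs = hm.pair_sexes(table)
        assert len(pairs) == 80

    def test_incomplete_pair_dropped(self):
        rows = _survey("a", "X", 160.0, 172.0) + _survey("b", "Y", 158.0, None)
        rows += _survey("c", "Z", 161.0, 173.0)
        pairs = hm.pair_sexes(pd.DataFrame(rows))
        assert set(pairs["country"]) == {"X", "Z"}

    def test_general_preferred_over_urban(self):
        rows = _survey("a", "X", 160.0, 172.0, setting="urban")
        rows += _survey("b", "X", 159.0, 171.0, setting="general")
        rows += _survey("c", "Y", 158.0, 170.0)
        pairs = hm.pair_sexes(pd.DataFrame(rows))
        assert list(pairs[pairs.country == "X"]["population_id"]) == ["b"]

    def test_age_closest_to_21_preferred(self):
        rows = _survey("a", "X", 160.0, 172.0, age_low=25, age_high=53)
        rows += _survey("b", "X", 159.0, 171.0, age_low=21, age_high=49)
        rows += _survey("c", "Y", 158.0, 170.0)
        pairs = hm.pair_sexes(pd.DataFrame(rows))
        assert list(pairs[pairs.country == "X"]["population_id"]) == ["b"]

    def test_wider_age_interval_preferred(self):
        rows = _survey("a", "X", 160.0, 172.0, age_low=21, age_high=30)
        rows += _survey("b", "X", 159.0, 171.0, age_low=21, age_high=60)
        rows += _survey("c", "Y", 158.0, 170.0)
        pairs = hm.pair_sexes(pd.DataFrame(rows))
        assert list(pairs[pairs.country == "X"]["population_id"]) == ["b"]

    def test_ethnic_groups_kept_separate(self):
        rows = _survey("a", "X", 160.0, 172.0, ethnic_group="g1")
        rows += _survey("b", "X", 156.0, 168.0, ethnic_group="g2")
        pairs = hm.pair_sexes(pd.DataFrame(rows))
        assert len(pairs) == 2

    def test_deduplication_idempotent(self):
        table = simulate_worldwide_survey_table(seed=3)
        pairs = hm.pair_sexes(table)
        # feed the retained pairs back in long format
        long = pd.concat(
            [
                pairs.assign(sex=0, mean_height=pairs["female_mean"]),
                pairs.assign(sex=1, mean_height=pairs["male_mean"]),
            ]
        )[["population_id", "country", "ethnic_group", "setting",
           "age_low", "age_high", "sex", "mean_height"]]
        again = hm.pair_sexes(long)
        assert len(again) == len(pairs)
        assert list(again["population_id"]) == list(pairs["population_id"])

    def test_missing_metadata_raises(self):
        df = pd.DataFrame(_survey("a", "X", 160.0, 172.0)).drop(columns=["setting"])
        with pytest.raises(ConfigurationError):
            hm.pair_sexes(df)


class TestScalingReport:
    def test_exact_proportional_sd(self):
        means = np.linspace(150, 165, 10)
        df = pd.DataFrame(
            {"population_id": [f"p{i}" for i in range(10)], "sex": 0,
             "mean_height": means, "sd_height": 0.04 * means, "n": 5000}
        )
        sd_fit, cv_fit = hm.scaling_report(df)
        assert sd_fit.slope == pytest.approx(0.04, abs=1e-12)
        assert sd_fit.adj_r2 == pytest.approx(1.0)
        assert abs(cv_fit.slope) < 1e-12

    def test_degenerate_means(self):
        df = pd.DataFrame(
            {"population_id": list("abc"), "sex": 0, "mean_height": 160.0,
             "sd_height": [6.1, 6.0, 6.2], "n": 5000}
        )
        with pytest.raises(SingularFitError):
            hm.scaling_report(df)
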