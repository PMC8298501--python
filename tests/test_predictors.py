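"""QC rules, weight-table filtering, PGHS and residual-predictor construction."""

import numpy as np
import pandas as pd
import pytest

import heightmodels as hm
from heightmodels.exceptions import ConfigurationError, DomainError, SingularFitError
from heightmodels.predictors import standardize_by_group


class TestOutlierQC:
    def test_planted_outlier_removed(self, rng):
        h = rng.normal(170, 6, size=5000)
        h = np.clip(h, 170 - 4 * 6, 170 + 4 * 6)
        h[0] = 170 + 5.2 * 6
        co = pd.DataFrame({"group": 1, "sex": 0, "height_cm": h})
        kept = hm.qc_exclude_outliers(co, sd_cut=4.75)
        assert len(kept) == 4999
        assert 0 not in kept.index

    def test_all_equal_none_removed(self):
        co = pd.DataFrame({"group": 1, "sex": [0, 0, 1, 1], "height_cm": 170.0})
        assert len(hm.qc_exclude_outliers(co)) == 4

    def test_tiny_stratum_passed_through(self):
        co = pd.DataFrame({"group": [1, 1, 2], "sex": [0, 1, 0],
                           "height_cm": [160.0, 175.0, 500.0]})
        with pytest.warns(UserWarning):
            kept = hm.qc_exclude_outliers(co)
        assert len(kept) == 3

    def test_large_cohort_exact_count(self, rng):
        """32 planted extreme values in a 369,185-row cohort leave 369,153."""
        n = 369_185 - 32
        groups = rng.integers(1, 7, size=n)
        sex = rng.integers(0, 2, size=n)
        h = rng.normal(165 + 13 * sex, 6.2)
        h = np.clip(h, 165 + 13 * sex - 4.2 * 6.2, 165 + 13 * sex + 4.2 * 6.2)
        extra = pd.DataFrame(
            {"group": rng.integers(1, 7, size=32), "sex": rng.integers(0, 2, size=32)}
        )
        extra["height_cm"] = 165 + 13 * extra["sex"] + 6.2 * 6.0
        co = pd.concat(
            [pd.DataFrame({"group": groups, "sex": sex, "height_cm": h}), extra],
            ignore_index=True,
        )
        kept = hm.qc_exclude_outliers(co, sd_cut=4.75)
        assert len(kept) == 369_153


class TestWeightTableFilter:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(6)],
                "locus_id": ["L1", "L1", "L1", "L2", "L3", "L3"],
                "p_value": [1e-12, 1e-9, 1e-15, 1e-11, 1e-8, 1e-8],
                "info": [0.95, 0.99, 0.92, 0.85, 0.97, 0.97],
                "weight": 0.1,
            }
        )

    def test_lowest_p_per_locus(self, table):
        out = hm.filter_weight_table(table)
        assert list(out["snp_id"]) == ["rs2", "rs3", "rs4"]

    def test_tie_breaks_by_snp_id(self, table):
        out = hm.filter_weight_table(table)
        # L3 has rs4/rs5 tied at 1e-8 -> lexicographically first kept
        assert "rs4" in list(out["snp_id"]) and "rs5" not in list(out["snp_id"])

    def test_thresholds_by_enumeration(self, table):
        out = hm.filter_weight_table(
            table, thresholds={"p_value": ("<", 5e-10), "info": (">", 0.9)}
        )
        # by hand: per-locus survivors rs2 (1e-15, .92), rs3 (1e-11, .85),
        # rs4 (1e-8, .97); thresholds keep only rs2
        assert list(out["snp_id"]) == ["rs2"]

    def test_all_pass_unchanged(self, table):
        one_per_locus = hm.filter_weight_table(table)
        again = hm.filter_weight_table(one_per_locus, thresholds={"info": (">", 0.0)})
        pd.testing.assert_frame_equal(again, one_per_locus)

    def test_drop_list_and_missing_column(self, table):
        out = hm.filter_weight_table(table, drop_snps=["rs2"])
        assert "rs2" not in list(out["snp_id"])
        with pytest.raises(ConfigurationError):
            hm.filter_weight_table(table, thresholds={"eaf_diff": ("<", 0.05)})


class TestPGHS:
    def test_single_snp_closed_form(self):
        geno = pd.DataFrame({"rs1": [0, 1, 2]})
        weights = pd.DataFrame(
            {"snp_id": ["rs1"], "effect_allele": ["A"], "weight": [1.0]}
        )
        score, _ = hm.compute_pghs(geno, weights, np.ones(3))
        expected = np.array([-1, 0, 1]) / np.sqrt(2 / 3)
        np.testing.assert_allclose(score, expected, atol=1e-12)

    def test_per_group_standardization(self, lognormal_pipeline):
        _, cohort, predictors = lognormal_pipeline
        for name, v in (("pghs", predictors.pghs), ("rp", predictors.rp)):
            df = pd.DataFrame({"g": cohort["group"].to_numpy(), "v": v})
            means = df.groupby("g")["v"].mean()
            var = df.groupby("g")["v"].apply(lambda s: s.var(ddof=0))
            assert means.abs().max() < 1e-10, name
            assert np.allclose(var, 1.0, atol=1e-8), name

    def test_orientation_flip_invariance(self, rng):
        geno = pd.DataFrame(
            rng.integers(0, 3, size=(500, 10)), columns=[f"rs{i}" for i in range(10)]
        )
        w = rng.normal(size=10)
        weights = pd.DataFrame(
            {"snp_id": geno.columns, "effect_allele": "A", "weight": w}
        )
        flipped = weights.copy()
        flip = rng.random(10) < 0.5
        flipped.loc[flip, "weight"] = -flipped.loc[flip, "weight"]
        geno_flipped = geno.copy()
        geno_flipped.loc[:, flip] = 2 - geno_flipped.loc[:, flip]
        groups = rng.integers(1, 3, size=500)
        a, _ = hm.compute_pghs(geno, weights, groups)
        b, _ = hm.compute_pghs(geno_flipped, flipped, groups)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_missing_snp_warned_and_dropped(self, rng):
        geno = pd.DataFrame({"rs1": rng.integers(0, 3, 100)})
        weights = pd.DataFrame(
            {"snp_id": ["rs1", "rs_absent"], "effect_allele": "A", "weight": [1.0, 2.0]}
        )
        with pytest.warns(UserWarning, match="absent"):
            score, _ = hm.compute_pghs(geno, weights, np.ones(100))
        assert score.shape == (100,)

    def test_recovers_genetic_signal(self, lognormal_pipeline):
        """Log-height regressed on PGHS recovers the generative genetic SD."""
        sim, cohort, predictors = lognormal_pipeline
        import math

        w_cm = sim.weights["weight"].to_numpy()
        w_log = w_cm / (10 ** float(np.mean(sim.truth.baseline_log_mean)) * math.log(10))
        het = 2 * sim.mafs * (1 - sim.mafs)
        sigma_g = math.sqrt(float(np.sum(w_log**2 * het)))
        y = np.log10(cohort["height_cm"].to_numpy())
        sex = cohort["sex"].to_numpy(float)
        X = np.column_stack([np.ones(len(y)), sex, predictors.pghs])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        # slope per 1 SD of PGHS equals the genetic log-scale SD
        assert beta[2] == pytest.approx(sigma_g, rel=0.1)


class TestResidualPredictor:
    def test_orthogonal_to_sex_and_pghs(self, lognormal_pipeline):
        _, cohort, predictors = lognormal_pipeline
        sex = cohort["sex"].to_numpy(float)
        assert abs(np.corrcoef(predictors.rp, sex)[0, 1]) < 1e-6
        assert abs(np.corrcoef(predictors.rp, predictors.pghs)[0, 1]) < 1e-6

    def test_recovers_generative_covariate(self, lognormal_pipeline):
        sim, cohort, predictors = lognormal_pipeline
        truth_rp = cohort["rp"].to_numpy()
        assert np.corrcoef(predictors.rp, truth_rp)[0, 1] > 0.9

    def test_no_covariates_raises(self, lognormal_pipeline):
        _, cohort, predictors = lognormal_pipeline
        with pytest.raises(DomainError):
            hm.compute_residual_predictor(cohort, predictors.pghs, covariates=[])

    def test_collinear_covariate_raises(self, lognormal_pipeline):
        _, cohort, predictors = lognormal_pipeline
        co = cohort.copy()
        co["sex_copy"] = co["sex"].astype(float)
        with pytest.raises(SingularFitError):
            hm.compute_residual_predictor(co, predictors.pghs,
                                          covariates=["rp", "sex_copy"])

    def test_constant_score_flagged(self):
        with pytest.raises(DomainError):
            standardize_by_group(np.ones(10), np.ones(10))
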