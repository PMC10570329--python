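"""Synthetic cohort generator: determinism, algebraic identities, marginals,
missingness mechanism, and the calibration search's simple solves."""
import copy

import numpy as np
import pandas as pd
import pytest

from ironpred import schema
from ironpred.config import ConfigError, GeneratorConfig
from ironpred.generate import (
    _McDesign,
    any_missing_fraction,
    calibrate_generator,
    generate_cohort,
    impose_missingness,
)
from ironpred.mi import ImputedStack
from ironpred.models import ModelSpec, fit_full


class TestGenerateCohort:
    def test_bit_identical_given_seed(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, small_config, small_cohort):
        other = generate_cohort(small_config.replace(seed=small_config.seed + 1))
        assert not other["ferritin"].equals(small_cohort["ferritin"])

    def test_row_count_and_strata(self, small_config, small_cohort):
        assert len(small_cohort) == small_config.n_pre + small_config.n_post
        meno = small_cohort[schema.MENOPAUSE_COLUMN]
        assert (meno == 0).sum() == small_config.n_pre
        assert (meno == 1).sum() == small_config.n_post

    def test_saturation_identity_holds_exactly(self, small_cohort):
        """TS = 100*iron/(iron+uibc) is an algebraic identity of the generator."""
        iron = small_cohort["serum_iron"]
        uibc = small_cohort["uibc"]
        ts = small_cohort["transferrin_saturation"]
        np.testing.assert_allclose(ts, 100 * iron / (iron + uibc), rtol=1e-9)

    def test_outcomes_positive_and_ts_bounded(self, small_cohort):
        for col in schema.OUTCOME_COLUMNS:
            assert (small_cohort[col] > 0).all()
        assert (small_cohort["transferrin_saturation"] < 100).all()

    def test_postmenopause_only_variables_structurally_missing(self, small_cohort):
        pre = small_cohort[small_cohort[schema.MENOPAUSE_COLUMN] == 0]
        post = small_cohort[small_cohort[schema.MENOPAUSE_COLUMN] == 1]
        for var in schema.POST_ONLY_PREDICTORS:
            assert pre[var].isna().all()
            assert post[var].notna().all()

    def test_reproductive_variables_consistent(self, small_cohort):
        post = small_cohort[small_cohort[schema.MENOPAUSE_COLUMN] == 1]
        assert (post["years_since_lmp"] > 0).all()
        assert (post["age"] - post["years_since_lmp"] > 25).all()  # age at menopause
        assert post["reproductive_lifespan"].between(15, 50).all()

    def test_zero_effects_vanishing_noise_gives_intercept_only_outcome(self, small_config):
        """With all coefficients zero and sigma -> 0, every ln-outcome equals
        the stratum intercept and a fitted model explains ~nothing."""
        betas = {o: {s: {} for s in ("pre", "post")} for o in
                 ("ferritin", "serum_iron", "transferrin_saturation")}
        sigma = {o: {"pre": 1e-3, "post": 1e-3} for o in betas}
        cfg = small_config.replace(betas=betas, sigma=sigma, seed=5,
                                   n_pre=2000, n_post=0,
                                   n_all_missing_outcomes=0, n_menopause_missing=0)
        cohort, truth = generate_cohort(cfg, return_truth=True)
        icept = truth["intercepts"]["ferritin"]["pre"]
        assert np.abs(np.log(cohort["ferritin"]) - icept).max() < 0.01
        stack = ImputedStack(m=1, datasets=[cohort], seed=0)
        fitted = fit_full(stack, ModelSpec("ln_ferritin", "pre"))
        # apparent R² on pure noise is the overfitting floor p/(n-1), ~0.008
        assert fitted.r2_apparent < 0.05

    def test_iron_median_within_published_iqr(self, default_observed):
        """Stratum serum-iron medians fall inside the published IQR [74, 115]."""
        for stratum_val in (0.0, 1.0):
            med = default_observed.loc[
                default_observed[schema.MENOPAUSE_COLUMN] == stratum_val, "serum_iron"
            ].median()
            assert 74.0 <= med <= 115.0

    def test_marginal_fidelity_at_large_n(self, default_config):
        cfg = default_config.replace(n_pre=25_000, n_post=25_000,
                                     n_all_missing_outcomes=0,
                                     n_menopause_missing=0, seed=33)
        cohort = generate_cohort(cfg)
        pre = cohort[cohort[schema.MENOPAUSE_COLUMN] == 0]
        post = cohort[cohort[schema.MENOPAUSE_COLUMN] == 1]
        # binary prevalences within one point of configured values
        for var in ("blood_donation_12mo", "statin", "aspirin"):
            for sub, stratum in ((pre, "pre"), (post, "post")):
                want = cfg.covariates[var][stratum]["p"]
                assert abs(sub[var].mean() - want) < 0.01
        # continuous medians within 2% of configured locations
        assert abs(pre["bmi"].median() / 25.91 - 1) < 0.02
        assert abs(post["age"].median() / 59.5 - 1) < 0.02
        assert abs(pre["dietary_supp_iron"].median() / 18.7 - 1) < 0.02


class TestConfigValidation:
    def test_unknown_coefficient_key_rejected(self, small_config):
        betas = copy.deepcopy(small_config.betas)
        betas["ferritin"]["pre"]["no_such_variable"] = 1.0
        with pytest.raises(ConfigError, match="no_such_variable"):
            small_config.replace(betas=betas)

    def test_bad_prevalence_rejected(self, small_config):
        cov = copy.deepcopy(small_config.covariates)
        cov["statin"]["pre"]["p"] = 1.7
        with pytest.raises(ConfigError, match="prevalence"):
            small_config.replace(covariates=cov)

    def test_nonpositive_sigma_rejected(self, small_config):
        sigma = copy.deepcopy(small_config.sigma)
        sigma["ferritin"]["pre"] = 0.0
        with pytest.raises(ConfigError, match="residual SD"):
            small_config.replace(sigma=sigma)

    def test_degenerate_correlation_rejected(self, small_config):
        with pytest.raises(ConfigError):
            small_config.replace(residual_corr={"iron_ts": 1.0,
                                                "ferritin_iron": 0.2,
                                                "ferritin_ts": 0.3})

    def test_missing_rate_outside_unit_interval_rejected(self, small_config):
        miss = copy.deepcopy(small_config.missingness)
        miss["predictor_rates"]["bmi"]["pre"] = 1.2
        with pytest.raises(ConfigError, match="missing rate"):
            small_config.replace(missingness=miss)


class TestImposeMissingness:
    def test_zero_rates_identity(self, small_config, small_cohort):
        miss = copy.deepcopy(small_config.missingness)
        for rates in miss["predictor_rates"].values():
            for k in rates:
                rates[k] = 0.0
        miss["outcome_rates"] = {k: 0.0 for k in miss["outcome_rates"]}
        cfg = small_config.replace(missingness=miss, n_all_missing_outcomes=0,
                                   n_menopause_missing=0)
        out = impose_missingness(small_cohort, cfg)
        pd.testing.assert_frame_equal(out, small_cohort)

    def test_exact_all_missing_outcome_count(self, default_observed):
        mask = default_observed[schema.SERUM_MARKERS].isna().all(axis=1)
        assert int(mask.sum()) == 29

    def test_menopause_missing_count(self, default_observed):
        assert int(default_observed[schema.MENOPAUSE_COLUMN].isna().sum()) == 2

    def test_deterministic_given_seed(self, small_config, small_cohort):
        a = impose_missingness(small_cohort, small_config)
        b = impose_missingness(small_cohort, small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_rate_caps_respected(self, default_observed, default_config):
        caps = default_config.missingness["rate_caps"]
        for var, rates in default_config.missingness["predictor_rates"].items():
            for stratum, rate in rates.items():
                assert rate <= caps[stratum] + 1e-9

    def test_ts_missing_wherever_iron_or_uibc_missing(self, default_observed):
        broken = default_observed["serum_iron"].isna() | default_observed["uibc"].isna()
        assert default_observed.loc[broken, "transferrin_saturation"].isna().all()


class TestCalibrateGenerator:
    def test_prevalence_target_sets_bernoulli_p(self, small_config):
        cfg = calibrate_generator({"prevalence:blood_donation_12mo:all": 0.14},
                                  base_config=small_config, n_mc=2000)
        assert cfg.covariates["blood_donation_12mo"]["pre"]["p"] == pytest.approx(0.14)
        assert cfg.covariates["blood_donation_12mo"]["post"]["p"] == pytest.approx(0.14)

    def test_median_target_sets_symmetric_location(self, small_config):
        cfg = calibrate_generator({"median:bmi:pre": 26.52},
                                  base_config=small_config, n_mc=2000)
        assert cfg.covariates["bmi"]["pre"]["loc"] == pytest.approx(26.52)

    def test_population_r2_target_solved_by_monte_carlo(self, small_config):
        """sigma solves R² = Var(Xb)/(Var(Xb)+sigma²) for the requested value."""
        target = 0.134
        cfg = calibrate_generator({"population_r2:ferritin:pre": target},
                                  base_config=small_config, n_mc=40_000,
                                  tolerances={"population_r2": 0.2})  # small-n check noise
        mc = _McDesign(cfg, 40_000, cfg.seed + 1)
        ve = mc.explained_var("ferritin", "pre")
        achieved = ve / (ve + cfg.sigma["ferritin"]["pre"] ** 2)
        assert achieved == pytest.approx(target, abs=0.02)

    def test_any_missing_target_scales_rates(self, small_config):
        cfg = calibrate_generator({"any_missing:pre": 0.10},
                                  base_config=small_config, n_mc=20_000)
        big = cfg.replace(n_pre=20_000, n_post=100, n_all_missing_outcomes=0,
                          n_menopause_missing=0, seed=9)
        observed = impose_missingness(generate_cohort(big), big)
        assert any_missing_fraction(observed, "pre") == pytest.approx(0.10, abs=0.02)
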