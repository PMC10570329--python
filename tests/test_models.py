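"""Model fitting under MI, backward elimination, and the stacked lasso."""
import numpy as np
import pandas as pd
import pytest

from ironpred import schema
from ironpred.generate import generate_cohort
from ironpred.mi import ImputedStack
from ironpred.models import (
    ModelError,
    ModelSpec,
    _solve_lasso,
    _stacked_arrays,
    _weighted_standardize,
    backward_select,
    build_design,
    fit_full,
    fit_univariable,
    lambda_max,
    stacked_lasso,
)


def single_effect_config(default_config, beta, sigma=0.4, n=2000, seed=71):
    """Premenopausal stratum whose only true effect is on ferritin."""
    betas = {o: {s: {} for s in ("pre", "post")}
             for o in ("ferritin", "serum_iron", "transferrin_saturation")}
    betas["ferritin"]["pre"] = dict(beta)
    sig = {o: {"pre": sigma, "post": sigma} for o in betas}
    return default_config.replace(
        betas=betas, sigma=sig, n_pre=n, n_post=0,
        n_all_missing_outcomes=0, n_menopause_missing=0, seed=seed,
    )


def complete_stack(cfg, m=1):
    return ImputedStack(m=m, datasets=[generate_cohort(cfg)] * m, seed=0)


class TestFitFull:
    def test_noiseless_limit_recovers_truth(self, default_config):
        cfg = single_effect_config(
            default_config,
            {"blood_donation_12mo": -0.7, "bmi": 0.02, "alcohol": 0.008},
            sigma=1e-5, n=1500,
        )
        fitted = fit_full(complete_stack(cfg), ModelSpec("ln_ferritin", "pre"))
        assert fitted.r2_apparent > 0.999999
        assert fitted.coefficients["blood_donation_12mo"].qbar == pytest.approx(-0.7, abs=1e-4)
        assert fitted.coefficients["bmi"].qbar == pytest.approx(0.02, abs=1e-5)
        assert fitted.coefficients["statin"].qbar == pytest.approx(0.0, abs=1e-4)

    def test_published_scale_donation_coefficient(self, medium_pre_stack):
        """The calibrated premenopausal generator carries the published
        blood-donation effect on ln(ferritin)."""
        fitted = fit_full(medium_pre_stack, ModelSpec("ln_ferritin", "pre"))
        est = fitted.coefficients["blood_donation_12mo"]
        assert est.qbar == pytest.approx(-0.700, abs=3 * est.se)

    def test_rank_deficient_design_reported(self, small_stack):
        broken = [df.assign(dup=df["bmi"]) for df in small_stack.datasets]
        stack = ImputedStack(m=len(broken), datasets=broken, seed=0)
        spec = ModelSpec("ln_ferritin", "pre",
                         schema.PREDICTORS_BY_STRATUM["pre"] + ["dup"])
        with pytest.raises(ModelError, match="collinear"):
            fit_full(stack, spec)

    def test_calcium_modeled_in_decigrams(self, small_stack):
        spec_dg = ModelSpec("ln_ferritin", "pre")
        spec_mg = ModelSpec("ln_ferritin", "pre", transforms={})
        in_dg = fit_full(small_stack, spec_dg).coefficients["dietary_supp_calcium"].qbar
        in_mg = fit_full(small_stack, spec_mg).coefficients["dietary_supp_calcium"].qbar
        assert in_dg == pytest.approx(100 * in_mg, rel=1e-8)

    def test_combined_spec_requires_menopause(self):
        with pytest.raises(ModelError, match="menopause"):
            ModelSpec("ln_ferritin", "combined", predictors=["age", "bmi"])

    def test_mi_and_complete_fits_agree_without_missingness(self, small_config):
        complete = generate_cohort(small_config)
        from ironpred.mi import impute

        stack = impute(complete, m=3, n_iter=2, seed=1)
        spec = ModelSpec("ln_ferritin", "pre")
        pooled = fit_full(stack, spec)
        single = fit_full(ImputedStack(m=1, datasets=[complete], seed=0), spec)
        assert pooled.coefficients["bmi"].qbar == pytest.approx(
            single.coefficients["bmi"].qbar
        )
        assert pooled.coefficients["bmi"].B == pytest.approx(0.0, abs=1e-20)


class TestUnivariable:
    def test_single_true_effect_isolated(self, default_config):
        cfg = single_effect_config(default_config, {"blood_donation_12mo": -0.7},
                                   sigma=0.3, n=3000)
        stack = complete_stack(cfg)
        don = fit_univariable(stack, "blood_donation_12mo", "ln_ferritin", "pre")
        assert don.qbar == pytest.approx(-0.7, abs=3 * don.se)
        null = fit_univariable(stack, "statin", "ln_ferritin", "pre")
        assert abs(null.qbar) < 3 * null.se

    def test_age_is_not_a_screenable_predictor(self, small_stack):
        with pytest.raises(ModelError, match="age"):
            fit_univariable(small_stack, "age", "ln_ferritin", "pre")

    def test_constant_predictor_rejected(self, small_stack):
        frames = [df.assign(statin=1.0) for df in small_stack.datasets]
        stack = ImputedStack(m=len(frames), datasets=frames, seed=0)
        with pytest.raises(ModelError, match="statin"):
            fit_univariable(stack, "statin", "ln_ferritin", "pre")

    @pytest.mark.parametrize("outcome", ["ln_ferritin", "ln_iron", "ln_ts"])
    def test_donation_slope_inverse_for_all_outcomes(self, medium_pre_stack, outcome):
        """Recent blood donation predicts lower values of every serum marker."""
        est = fit_univariable(medium_pre_stack, "blood_donation_12mo", outcome, "pre")
        assert est.qbar < 0
        assert est.p_value < 0.05


class TestBackwardSelect:
    def test_all_strong_predictors_survive_with_empty_path(self, default_config):
        cfg = single_effect_config(
            default_config,
            {"blood_donation_12mo": -0.8, "bmi": 0.05, "alcohol": 0.03},
            sigma=0.3, n=1500,
        )
        spec = ModelSpec("ln_ferritin", "pre", ["blood_donation_12mo", "bmi", "alcohol"])
        result = backward_select(complete_stack(cfg), spec)
        assert result.selected == spec.predictors
        assert result.path == []

    def test_pure_noise_predictors_all_removed_at_strict_threshold(self, default_config):
        cfg = single_effect_config(default_config, {}, sigma=1.0, n=800, seed=55)
        result = backward_select(complete_stack(cfg),
                                 ModelSpec("ln_ferritin", "pre"), p_threshold=0.001)
        assert result.selected == []
        assert result.final_model is None

    def test_termination_and_exit_pvalues(self, small_stack):
        spec = ModelSpec("ln_ferritin", "pre")
        result = backward_select(small_stack, spec, p_threshold=0.05)
        assert len(result.path) <= len(spec.predictors)
        if result.final_model is not None:
            for name in result.selected:
                assert result.final_model.coefficients[name].p_value < 0.05

    def test_strong_synthetic_effects_always_selected(self, medium_pre_stack):
        result = backward_select(medium_pre_stack, ModelSpec("ln_ferritin", "pre"))
        assert "blood_donation_12mo" in result.selected
        assert "ida_ever" in result.selected


class TestStackedLasso:
    def test_unpenalized_limit_equals_weighted_ols(self, small_stack):
        spec = ModelSpec("ln_ferritin", "pre")
        X, y, w, _ = _stacked_arrays(small_stack, spec)
        Xs, yc, *_ = _weighted_standardize(X, y, w)
        b0 = _solve_lasso(Xs, yc, w, 0.0)
        sw = np.sqrt(w / w.sum() * len(yc))
        oracle, *_ = np.linalg.lstsq(Xs * sw[:, None], yc * sw, rcond=None)
        np.testing.assert_allclose(b0, oracle, atol=1e-6)

    def test_lambda_max_zeroes_every_coefficient(self, small_stack):
        spec = ModelSpec("ln_ferritin", "pre")
        X, y, w, _ = _stacked_arrays(small_stack, spec)
        lmax = lambda_max(X, y, w)
        Xs, yc, *_ = _weighted_standardize(X, y, w)
        assert np.all(_solve_lasso(Xs, yc, w, lmax * (1 + 1e-6)) == 0.0)
        # just below the threshold at least one coefficient activates
        assert np.any(_solve_lasso(Xs, yc, w, lmax * 0.99) != 0.0)

    def test_nonzero_count_monotone_in_lambda(self, small_stack):
        result = stacked_lasso(small_stack, ModelSpec("ln_ferritin", "pre"), seed=3)
        path = result.path[0]
        order = np.argsort(path["lambda_grid"])
        nz = np.array(path["n_nonzero"])[order]
        assert np.all(np.diff(nz) <= 0)

    def test_strong_predictor_kept_noise_mostly_dropped(self, default_config):
        kept_strong, noise_frac = [], []
        for seed in range(3):
            cfg = single_effect_config(default_config, {"blood_donation_12mo": -0.8},
                                       sigma=0.5, n=1000, seed=300 + seed)
            result = stacked_lasso(complete_stack(cfg),
                                   ModelSpec("ln_ferritin", "pre"), seed=seed)
            kept_strong.append("blood_donation_12mo" in result.selected)
            noise = [v for v in result.selected if v != "blood_donation_12mo"]
            noise_frac.append(len(noise) / 15)
        assert all(kept_strong)
        assert np.mean(noise_frac) <= 0.3  # >= 70% of noise predictors excluded

    def test_elastic_net_not_supported(self, small_stack):
        with pytest.raises(ModelError, match="alpha"):
            stacked_lasso(small_stack, ModelSpec("ln_ferritin", "pre"), alpha=0.5)

    def test_empty_grid_rejected(self, small_stack):
        with pytest.raises(ModelError, match="grid"):
            stacked_lasso(small_stack, ModelSpec("ln_ferritin", "pre"),
                          lambda_grid=np.array([]))

    def test_grouped_folds_are_deterministic(self, small_stack):
        spec = ModelSpec("ln_ferritin", "pre")
        a = stacked_lasso(small_stack, spec, seed=9)
        b = stacked_lasso(small_stack, spec, seed=9)
        assert a.selected == b.selected
        assert a.path[0]["lambda_best"] == b.path[0]["lambda_best"]


class TestBuildDesign:
    def test_missing_predictor_column_reported(self, small_stack):
        spec = ModelSpec("ln_ferritin", "pre", ["age", "bmi"])
        df = small_stack.datasets[0].drop(columns=["bmi"])
        with pytest.raises(ModelError, match="bmi"):
            build_design(df, spec)

    def test_outcome_on_log_scale(self, small_stack):
        df = small_stack.datasets[0]
        y, X = build_design(df, ModelSpec("ln_ferritin", "pre", ["age"]))
        pre = df[df[schema.MENOPAUSE_COLUMN] == 0]
        np.testing.assert_allclose(np.sort(y), np.sort(np.log(pre["ferritin"])))
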