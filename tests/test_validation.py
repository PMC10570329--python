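"""R², calibration slopes and the bootstrap optimism machinery."""
import numpy as np
import pandas as pd
import pytest

from ironpred import schema
from ironpred.mi import ImputedStack
from ironpred.models import ModelSpec, build_design
from ironpred.validation import (
    ValidationError,
    bootstrap_optimism,
    calibration_slope,
    r_squared,
    validate_mi,
)


class TestRSquared:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_mean_prediction_explains_nothing(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_example(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValidationError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_may_be_negative_for_foreign_predictions(self):
        assert r_squared([1.0, 2.0, 3.0], [9.0, -4.0, 7.0]) < 0


class TestCalibrationSlope:
    def test_perfect_calibration(self):
        y = np.array([1.0, 2.0, 4.0])
        assert calibration_slope(y, y) == pytest.approx(1.0)

    def test_halved_predictions_give_slope_two(self):
        y = np.array([-2.0, 0.0, 2.0, 4.0])
        assert calibration_slope(y, y / 2) == pytest.approx(2.0)

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValidationError):
            calibration_slope([1.0, 2.0], [3.0, 3.0])


def null_frame(rng, n, p=16):
    df = pd.DataFrame(rng.standard_normal((n, p)),
                      columns=schema.PREDICTORS_BY_STRATUM["pre"][:p])
    df[schema.MENOPAUSE_COLUMN] = 0.0
    df["ferritin"] = np.exp(rng.standard_normal(n))
    return df


class TestBootstrapOptimism:
    def test_in_sample_slope_of_ols_fit_is_exactly_one(self, small_stack):
        """The apparent calibration slope of OLS on its own training data is 1
        by construction — only the bootstrap test-step slope is informative."""
        df = small_stack.datasets[0]
        y, X = build_design(df, ModelSpec("ln_ferritin", "pre"))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert calibration_slope(y, X @ beta) == pytest.approx(1.0, abs=1e-10)
        rep = bootstrap_optimism(df, ModelSpec("ln_ferritin", "pre"), B=2, seed=0)
        assert rep.slope_apparent == pytest.approx(1.0, abs=1e-10)

    def test_identity_resample_has_zero_optimism(self, small_stack):
        df = small_stack.datasets[0]
        rep = bootstrap_optimism(
            df, ModelSpec("ln_ferritin", "pre"), B=1, seed=0,
            _resampler=lambda rng, n: np.arange(n),
        )
        assert rep.optimism_r2 == pytest.approx(0.0, abs=1e-12)
        assert rep.r2_corrected == pytest.approx(rep.r2_apparent)
        assert rep.slope_internal == pytest.approx(1.0, abs=1e-10)

    def test_reproducible_given_seed(self, small_stack):
        df = small_stack.datasets[0]
        spec = ModelSpec("ln_ferritin", "pre")
        a = bootstrap_optimism(df, spec, B=25, seed=42)
        b = bootstrap_optimism(df, spec, B=25, seed=42)
        assert a.optimism_r2 == b.optimism_r2
        assert a.slope_internal == b.slope_internal

    def test_corrected_below_apparent_under_overfitting(self):
        rng = np.random.default_rng(8)
        rep = bootstrap_optimism(null_frame(rng, 150),
                                 ModelSpec("ln_ferritin", "pre"), B=100, seed=1)
        assert rep.optimism_r2 > 0
        assert rep.r2_corrected < rep.r2_apparent

    def test_test_step_r2_enters_untruncated(self):
        rng = np.random.default_rng(9)
        rep = bootstrap_optimism(null_frame(rng, 60),
                                 ModelSpec("ln_ferritin", "pre"), B=100, seed=2,
                                 keep_replicates=True)
        assert min(rep.replicates["r2_test"]) < 0  # negative values retained

    def test_optimism_shrinks_with_sample_size(self):
        rng = np.random.default_rng(10)
        small = np.mean([
            bootstrap_optimism(null_frame(rng, 100, p=8),
                               ModelSpec("ln_ferritin", "pre",
                                         schema.PREDICTORS_BY_STRATUM["pre"][:8]),
                               B=80, seed=s).optimism_r2
            for s in range(4)
        ])
        big = np.mean([
            bootstrap_optimism(null_frame(rng, 2000, p=8),
                               ModelSpec("ln_ferritin", "pre",
                                         schema.PREDICTORS_BY_STRATUM["pre"][:8]),
                               B=80, seed=s).optimism_r2
            for s in range(2)
        ])
        assert big < small

    def test_invalid_b_rejected(self, small_stack):
        with pytest.raises(ValidationError):
            bootstrap_optimism(small_stack.datasets[0],
                               ModelSpec("ln_ferritin", "pre"), B=0)


class TestValidateMI:
    def test_single_imputation_equals_direct_call(self, small_stack):
        stack1 = ImputedStack(m=1, datasets=[small_stack.datasets[0]], seed=0)
        spec = ModelSpec("ln_ferritin", "pre")
        pooled = validate_mi(stack1, spec, B=30, seed=5)
        direct = bootstrap_optimism(small_stack.datasets[0], spec, B=30,
                                    seed=pooled.per_imputation[0].seed)
        assert pooled.r2_apparent == pytest.approx(direct.r2_apparent)
        assert pooled.optimism_r2 == pytest.approx(direct.optimism_r2)
        assert pooled.slope_internal == pytest.approx(direct.slope_internal)

    def test_pooled_values_are_means_of_per_imputation(self, small_stack):
        rep = validate_mi(small_stack, ModelSpec("ln_ferritin", "pre"), B=20, seed=6)
        for attr in ("r2_apparent", "optimism_r2", "r2_corrected", "slope_internal"):
            per = [getattr(r, attr) for r in rep.per_imputation]
            assert getattr(rep, attr) == pytest.approx(float(np.mean(per)))

    def test_identical_datasets_agree_up_to_bootstrap_noise(self, small_stack):
        df = small_stack.datasets[0]
        stack = ImputedStack(m=3, datasets=[df] * 3, seed=0)
        rep = validate_mi(stack, ModelSpec("ln_ferritin", "pre"), B=150, seed=7)
        apparents = [r.r2_apparent for r in rep.per_imputation]
        assert max(apparents) - min(apparents) < 1e-12  # same data, same apparent
        optimisms = [r.optimism_r2 for r in rep.per_imputation]
        assert max(optimisms) - min(optimisms) < 0.05  # only bootstrap noise

    def test_report_round_trip(self, small_stack, tmp_path):
        rep = validate_mi(small_stack, ModelSpec("ln_ferritin", "pre"), B=10, seed=8)
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["r2_apparent"] == pytest.approx(rep.r2_apparent)
        assert len(loaded["per_imputation"]) == small_stack.m
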