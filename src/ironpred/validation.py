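"""Internal validation: apparent performance, bootstrap optimism, calibration.

Implements the resampling scheme for optimism-corrected performance:

1. fit the prediction model and compute performance on the observed data
   (the *apparent* statistics);
2. draw a bootstrap sample (with replacement, same n);
3. refit on the bootstrap sample and compute performance there (the
   *training* estimate);
4. apply the bootstrap-sample coefficients to the original data and compute
   performance (the *testing* estimate);
5. repeat B times; optimism = mean(training − testing), and the corrected
   statistic is apparent − optimism.

The calibration slope is the OLS slope of observed on predicted values; 1.0
is perfect calibration, below 1.0 means the model's predictions are more
extreme than the outcomes warrant (overfitting).  The in-sample slope of an
OLS fit is identically 1, so only the test-step slope is informative; its
bootstrap mean is reported as the internal-validation slope.

Under multiple imputation the whole procedure runs once per completed
dataset (independent child seeds) and the apparent, corrected and slope
statistics are averaged across imputations.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mi import ImputedStack
from .models import ModelSpec, build_design

logger = logging.getLogger(__name__)


class ValidationError(RuntimeError):
    pass


def r_squared(observed, predicted) -> float:
    """Proportion of explained variation, 1 − SSE/SST.

    SST is about the mean of ``observed``.  May be negative when predictions
    come from another sample's fit (the bootstrap test step); that is allowed
    and enters the optimism average untruncated.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValidationError("need two equal-length vectors of length >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValidationError("observed values are constant; R² undefined")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def calibration_slope(observed, predicted) -> float:
    """OLS slope of observed ~ intercept + predicted."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValidationError("need two equal-length vectors of length >= 2")
    var = float(np.var(pred))
    if var == 0:
        raise ValidationError("predicted values are constant; slope undefined")
    return float(np.cov(pred, obs, ddof=0)[0, 1] / var)


@dataclass
class ValidationReport:
    r2_apparent: float
    slope_apparent: float
    B: int
    optimism_r2: float
    r2_corrected: float
    slope_internal: float
    seed: int
    n: int = 0
    replicates: dict[str, list[float]] | None = None
    per_imputation: list["ValidationReport"] = field(default_factory=list)

    def to_json(self, path, include_replicates: bool = False) -> None:
        def encode(rep: "ValidationReport") -> dict:
            d = {
                "r2_apparent": rep.r2_apparent,
                "slope_apparent": rep.slope_apparent,
                "B": rep.B,
                "optimism_r2": rep.optimism_r2,
                "r2_corrected": rep.r2_corrected,
                "slope_internal": rep.slope_internal,
                "seed": rep.seed,
                "n": rep.n,
            }
            if include_replicates and rep.replicates is not None:
                d["replicates"] = rep.replicates
            if rep.per_imputation:
                d["per_imputation"] = [encode(r) for r in rep.per_imputation]
            return d

        Path(path).write_text(json.dumps(encode(self), indent=2), encoding="utf-8")


def _lstsq_fit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    return beta


def bootstrap_optimism(
    data,
    spec: ModelSpec,
    B: int = 200,
    seed: int = 0,
    max_redraws: int = 100,
    keep_replicates: bool = False,
    _resampler=None,
) -> ValidationReport:
    """Optimism-corrected R² and internal calibration slope on one dataset.

    ``data`` must be complete for the spec's variables (one imputation).  A
    bootstrap replicate with a rank-deficient design is redrawn (logged, with
    a redraw budget).  Deterministic given ``seed``.  ``_resampler`` is a test
    seam: a callable ``(rng, n) -> indices`` replacing the bootstrap draw.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    y, X = build_design(data, spec)
    n = len(y)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    beta_app = _lstsq_fit(y, X)
    pred_app = X @ beta_app
    r2_app = r_squared(y, pred_app)
    slope_app = calibration_slope(y, pred_app)

    draw = _resampler or (lambda rng_, n_: rng_.integers(0, n_, n_))
    r2_train, r2_test, slope_test = [], [], []
    redraws = 0
    for _ in range(B):
        while True:
            idx = draw(rng, n)
            try:
                beta_b = _lstsq_fit(y[idx], X[idx])
                break
            except np.linalg.LinAlgError:
                redraws += 1
                if redraws > max_redraws:
                    raise ValidationError("bootstrap redraw budget exhausted "
                                          "(persistently rank-deficient resamples)")
        r2_train.append(r_squared(y[idx], X[idx] @ beta_b))
        pred_test = X @ beta_b
        r2_test.append(r_squared(y, pred_test))
        slope_test.append(calibration_slope(y, pred_test))
    if redraws:
        logger.info("redrew %d rank-deficient bootstrap replicates", redraws)

    optimism = float(np.mean(np.array(r2_train) - np.array(r2_test)))
    return ValidationReport(
        r2_apparent=r2_app,
        slope_apparent=slope_app,
        B=B,
        optimism_r2=optimism,
        r2_corrected=r2_app - optimism,
        slope_internal=float(np.mean(slope_test)),
        seed=seed,
        n=n,
        replicates=(
            {"r2_train": r2_train, "r2_test": r2_test, "slope_test": slope_test}
            if keep_replicates else None
        ),
    )


def validate_mi(
    stack: ImputedStack, spec: ModelSpec, B: int = 200, seed: int = 0
) -> ValidationReport:
    """Bootstrap optimism correction per completed dataset, then averaged.

    Each imputation's bootstrap uses an independent child seed spawned from
    ``seed``; the pooled report is the arithmetic mean of the per-imputation
    apparent, optimism, corrected and slope statistics.
    """
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(seed).spawn(stack.m)
    ]
    reports = [
        bootstrap_optimism(df, spec, B=B, seed=child_seeds[i])
        for i, df in enumerate(stack.datasets)
    ]
    mean = lambda attr: float(np.mean([getattr(r, attr) for r in reports]))
    return ValidationReport(
        r2_apparent=mean("r2_apparent"),
        slope_apparent=mean("slope_apparent"),
        B=B,
        optimism_r2=mean("optimism_r2"),
        r2_corrected=mean("r2_corrected"),
        slope_internal=mean("slope_internal"),
        seed=seed,
        n=reports[0].n if reports else 0,
        per_imputation=reports,
    )
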