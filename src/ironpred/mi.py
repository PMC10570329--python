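"""Multiple imputation by chained equations and Rubin's-rules pooling.

The chained-equations engine fills missing predictor and outcome cells by
cycling per-variable conditional models: predictive-mean matching (type-1,
with a posterior draw of the regression coefficients and k donors) for
continuous variables, Bayesian logistic draws for binaries.  Imputation is
performed within menopause stratum, so structurally absent variables
(postmenopause-only history in premenopausal rows) are never modeled or
filled.  Outcomes participate in the imputation models on the ln scale and
may themselves be imputed when partially missing.

Pooling follows Rubin's rules: pooled point estimate = mean of per-imputation
estimates, total variance = within + (1 + 1/m) * between, with
Barnard–Rubin-style degrees of freedom.  Performance statistics (R²,
calibration slopes) are pooled by simple averaging across imputations.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import schema
from ._rng import stage_rng

logger = logging.getLogger(__name__)


class MIError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class ImputedStack:
    """m completed copies of a cohort plus provenance."""

    m: int
    datasets: list[pd.DataFrame]
    imputation_log: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.m != len(self.datasets):
            raise MIError("m does not match the number of completed datasets")

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets):
            df.to_csv(directory / f"imputation_{i:03d}.csv", index=False)
        manifest = {"m": self.m, "seed": self.seed, "log": self.imputation_log}
        with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    @classmethod
    def load(cls, directory) -> "ImputedStack":
        directory = Path(directory)
        with open(directory / "manifest.json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        datasets = [
            pd.read_csv(directory / f"imputation_{i:03d}.csv") for i in range(manifest["m"])
        ]
        return cls(m=manifest["m"], datasets=datasets,
                   imputation_log=manifest.get("log", {}), seed=manifest.get("seed", 0))


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of per-imputation (estimate, SE) pairs."""

    qbar: float
    W: float          # within-imputation variance, mean(se^2)
    B: float          # between-imputation variance, sample variance of estimates
    T: float          # total variance W + (1 + 1/m) B
    df: float
    se: float
    p_value: float
    m: int
    degenerate: bool = False  # m == 1: no between-imputation component

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        half = stats.t.ppf(0.5 + level / 2.0, self.df) * self.se
        return (self.qbar - half, self.qbar + half)


def pool_rubin(estimates, dfcom: float | None = None) -> PooledEstimate:
    """Combine per-imputation (estimate, se) pairs by Rubin's rules.

    With m = 1 the result is degenerate: T = W, B undefined (flagged), df from
    the complete-data fit if given.
    """
    pairs = list(estimates)
    if len(pairs) == 0:
        raise MIError("pool_rubin requires at least one (estimate, se) pair")
    q = np.array([p[0] for p in pairs], dtype=float)
    se = np.array([p[1] for p in pairs], dtype=float)
    m = len(pairs)
    qbar = float(q.mean())
    W = float(np.mean(se**2))
    if m == 1:
        T = W
        df = float(dfcom) if dfcom is not None else np.inf
        pooled_se = float(np.sqrt(T))
        p = _t_p_value(qbar, pooled_se, df)
        return PooledEstimate(qbar, W, np.nan, T, df, pooled_se, p, m, degenerate=True)
    B = float(np.var(q, ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if B > 0:
        r = (1.0 + 1.0 / m) * B / W if W > 0 else np.inf
        df = (m - 1) * (1.0 + 1.0 / r) ** 2
    else:
        df = np.inf
    if dfcom is not None:
        df = min(df, float(dfcom))
    pooled_se = float(np.sqrt(T))
    p = _t_p_value(qbar, pooled_se, df)
    return PooledEstimate(qbar, W, B, T, df, pooled_se, p, m)


def _t_p_value(q: float, se: float, df: float) -> float:
    if se == 0:
        return 0.0 if q != 0 else 1.0
    tstat = q / se
    if np.isinf(df):
        return float(2.0 * stats.norm.sf(abs(tstat)))
    return float(2.0 * stats.t.sf(abs(tstat), df))


@dataclass
class PooledPerformance:
    """Average of a per-imputation performance statistic, with its spread."""

    mean: float
    sd: float
    per_imputation: list[float]


def pool_performance(values) -> PooledPerformance:
    vals = [float(v) for v in values]
    if not vals:
        raise MIError("pool_performance requires at least one value")
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return PooledPerformance(mean=float(np.mean(vals)), sd=sd, per_imputation=vals)


# --------------------------------------------------------------------------
# chained equations
# --------------------------------------------------------------------------

def _pmm_impute(rng, y_obs, X_obs, X_mis, k: int) -> np.ndarray:
    """Type-1 predictive-mean matching with a posterior coefficient draw."""
    n_obs, p = X_obs.shape
    XtX = X_obs.T @ X_obs
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n_obs - p, 1)
    s2 = float(resid @ resid) / dof
    s2_star = s2 * dof / max(float(rng.chisquare(dof)), 1e-12)
    cov = s2_star * XtX_inv
    # symmetrize + jitter before factorization (pinv can break symmetry)
    cov = (cov + cov.T) / 2.0 + 1e-12 * np.eye(p)
    beta_star = beta_hat + np.linalg.cholesky(cov) @ rng.standard_normal(p)

    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_star
    kk = min(k, n_obs)
    out = np.empty(len(yhat_mis))
    for i in range(len(yhat_mis)):
        dist = np.abs(yhat_obs - yhat_mis[i])
        donors = np.argpartition(dist, kk - 1)[:kk] if kk < n_obs else np.arange(n_obs)
        out[i] = y_obs[donors[rng.integers(donors.size)]]
    return out


def _logistic_impute(rng, y_obs, X_obs, X_mis) -> np.ndarray:
    """Bayesian logistic draw; falls back to donor sampling on separation."""
    import warnings

    import statsmodels.api as sm

    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y_obs, X_obs, family=sm.families.Binomial()).fit(maxiter=50)
        if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 50):
            raise np.linalg.LinAlgError("unstable logistic fit")
        cov = np.asarray(fit.cov_params())
        cov = (cov + cov.T) / 2.0 + 1e-10 * np.eye(cov.shape[0])
        beta_star = np.asarray(fit.params) + np.linalg.cholesky(cov) @ rng.standard_normal(
            cov.shape[0]
        )
        p = expit(X_mis @ beta_star)
        return (rng.random(len(X_mis)) < p).astype(float)
    except Exception:
        logger.info("logistic imputation unstable; falling back to donor sampling")
        return rng.choice(y_obs, size=len(X_mis), replace=True)


def _impute_stratum(
    rng: np.random.Generator,
    frame: pd.DataFrame,
    binary_cols: set[str],
    n_iter: int,
    k_pmm: int = 5,
) -> pd.DataFrame:
    """One chained-equations chain over a fully numeric frame."""
    work = frame.copy()
    miss = {c: work[c].isna().to_numpy() for c in work.columns if work[c].isna().any()}
    for col, mask in miss.items():
        obs = work.loc[~mask, col].to_numpy()
        if obs.size == 0:
            raise MIError(f"variable {col!r} has no observed values in its stratum")
        work.loc[mask, col] = rng.choice(obs, size=int(mask.sum()), replace=True)

    # visit order: ascending missingness
    visit = sorted(miss, key=lambda c: miss[c].sum())
    cols = list(work.columns)
    for _ in range(n_iter):
        for col in visit:
            mask = miss[col]
            others = [c for c in cols if c != col]
            X = np.column_stack([np.ones(len(work)), work[others].to_numpy(dtype=float)])
            y = frame[col].to_numpy(dtype=float)  # observed truth where present
            X_obs, y_obs, X_mis = X[~mask], y[~mask], X[mask]
            if col in binary_cols:
                imputed = _logistic_impute(rng, y_obs, X_obs, X_mis)
            else:
                imputed = _pmm_impute(rng, y_obs, X_obs, X_mis, k=k_pmm)
            work.loc[mask, col] = imputed
    return work


def impute(
    cohort: pd.DataFrame,
    m: int = 5,
    n_iter: int = 10,
    seed: int = 0,
    k_pmm: int = 5,
) -> ImputedStack:
    """Create m completed copies of the cohort by chained equations.

    Operates within menopause stratum; rows with unknown menopause status are
    dropped (menopause defines the strata and is never imputed).  Outcomes are
    imputed on the ln scale; UIBC is rebuilt from iron and saturation so the
    saturation identity holds in every completed copy.  Deterministic given
    ``seed``; the m chains are independent.
    """
    if m < 1:
        raise MIError("m must be >= 1")

    meno = cohort[schema.MENOPAUSE_COLUMN]
    n_unknown = int(meno.isna().sum())
    base = cohort.loc[meno.notna()].copy()

    model_cols = {
        "pre": schema.PREDICTORS_BY_STRATUM["pre"],
        "post": schema.PREDICTORS_BY_STRATUM["post"],
    }
    # the assayed markers are the imputation primitives; transferrin
    # saturation is re-derived afterwards so its identity holds in every
    # completed copy
    ln_outcomes = {"ln_ferritin": "ferritin", "ln_iron": "serum_iron",
                   "ln_uibc": "uibc"}
    binary_cols = set(schema.BINARY_PREDICTORS)

    datasets = []
    for chain in range(m):
        rng = stage_rng(seed, "imputation", chain)
        completed = base.copy()
        for stratum, meno_val in (("pre", 0.0), ("post", 1.0)):
            rows = base.index[base[schema.MENOPAUSE_COLUMN] == meno_val]
            if len(rows) == 0:
                continue
            frame = base.loc[rows, model_cols[stratum]].copy()
            for ln_name, col in ln_outcomes.items():
                frame[ln_name] = np.log(base.loc[rows, col])
            filled = _impute_stratum(rng, frame, binary_cols, n_iter, k_pmm)
            completed.loc[rows, model_cols[stratum]] = filled[model_cols[stratum]].to_numpy()
            for ln_name, col in ln_outcomes.items():
                completed.loc[rows, col] = np.exp(filled[ln_name].to_numpy())
        completed["transferrin_saturation"] = (
            100.0 * completed["serum_iron"]
            / (completed["serum_iron"] + completed["uibc"])
        )
        _assert_observed_preserved(base, completed)
        datasets.append(completed)

    log = {
        "n_iter": n_iter,
        "k_pmm": k_pmm,
        "n_menopause_dropped": n_unknown,
        "method": {c: ("logistic" if c in binary_cols else "pmm")
                   for c in schema.ALL_PREDICTORS},
    }
    return ImputedStack(m=m, datasets=datasets, imputation_log=log, seed=seed)


def _assert_observed_preserved(source: pd.DataFrame, completed: pd.DataFrame) -> None:
    for col in source.columns:
        obs = source[col].notna()
        if col == "transferrin_saturation":
            # re-derived from iron and UIBC; equal to the stored value up to
            # floating-point round trip
            continue
        if not np.allclose(
            source.loc[obs, col].to_numpy(dtype=float),
            completed.loc[obs, col].to_numpy(dtype=float),
            equal_nan=False,
            rtol=1e-10, atol=1e-10,
        ):
            raise AssertionError(f"imputation altered observed cells of {col!r}")
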