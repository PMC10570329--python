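"""Linear prediction models under multiple imputation.

Univariable age-adjusted screens, the full multivariable OLS model with
Rubin-pooled coefficients, and the two variable-selection procedures:

* pooled backward elimination — fit the full model in every completed
  dataset, pool with Rubin's rules, repeatedly drop the predictor with the
  largest pooled p-value until all remaining p-values fall below the
  threshold;
* stacked lasso — stack the m completed datasets, weight every row 1/m so
  each participant carries unit total weight, and solve the L1-penalized
  least-squares path with the penalty chosen by participant-grouped K-fold
  cross-validation minimizing weighted MSE.

All outcomes are modeled on the natural-log scale; calcium enters in
decigrams via a spec-level transform (the stored data stay in mg).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso

from . import schema
from ._rng import stage_rng
from .mi import ImputedStack, PooledEstimate, pool_performance, pool_rubin

logger = logging.getLogger(__name__)

MODEL_TRANSFORMS = {"dietary_supp_calcium": 0.01}


class ModelError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# specs and containers
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Which outcome, which stratum, which predictors (in order)."""

    outcome: str                      # ln_ferritin | ln_iron | ln_ts
    stratum: str                      # pre | post | combined
    predictors: list[str] = field(default_factory=list)
    transforms: dict[str, float] = field(default_factory=lambda: dict(MODEL_TRANSFORMS))

    def __post_init__(self):
        if self.outcome not in schema.MODEL_OUTCOMES:
            raise ModelError(f"unknown outcome {self.outcome!r}")
        if self.stratum not in schema.PREDICTORS_BY_STRATUM:
            raise ModelError(f"unknown stratum {self.stratum!r}")
        if not self.predictors:
            self.predictors = list(schema.PREDICTORS_BY_STRATUM[self.stratum])
        if self.stratum == "combined" and schema.MENOPAUSE_COLUMN not in self.predictors:
            raise ModelError("combined-stratum spec must include the menopause indicator")

    @property
    def outcome_column(self) -> str:
        return schema.MODEL_OUTCOMES[self.outcome]

    def replace_predictors(self, predictors: list[str]) -> "ModelSpec":
        return ModelSpec(self.outcome, self.stratum, list(predictors), dict(self.transforms))


@dataclass
class FittedModel:
    spec: ModelSpec
    intercept: PooledEstimate
    coefficients: dict[str, PooledEstimate]
    n_used: int
    r2_apparent: float
    r2_per_imputation: list[float] = field(default_factory=list)

    def coefficient_table(self) -> pd.DataFrame:
        rows = {}
        for name, est in {"intercept": self.intercept, **self.coefficients}.items():
            lo, hi = est.ci()
            rows[name] = {"estimate": est.qbar, "se": est.se,
                          "ci_low": lo, "ci_high": hi, "p_value": est.p_value}
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class SelectionResult:
    method: str                   # backward | lasso
    selected: list[str]
    path: list[dict]
    final_model: FittedModel | None


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

def select_stratum(df: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "combined":
        return df.loc[df[schema.MENOPAUSE_COLUMN].notna()]
    meno = 1.0 if stratum == "post" else 0.0
    return df.loc[df[schema.MENOPAUSE_COLUMN] == meno]


def build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """(y, X-with-constant) for a completed dataset, transforms applied."""
    sub = select_stratum(df, spec.stratum)
    missing = [c for c in spec.predictors if c not in sub.columns]
    if missing:
        raise ModelError(f"predictors not in data: {missing}")
    X = sub[spec.predictors].to_numpy(dtype=float).copy()
    for j, c in enumerate(spec.predictors):
        X[:, j] *= spec.transforms.get(c, 1.0)
    y = np.log(sub[spec.outcome_column].to_numpy(dtype=float))
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    return y[keep], np.column_stack([np.ones(int(keep.sum())), X[keep]])


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via the R diagonal of a pivoted QR proxy
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [(["const"] + names)[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise ModelError(f"rank-deficient design; collinear columns: {bad or 'unknown'}")


def _ols(y: np.ndarray, X: np.ndarray):
    model = sm.OLS(y, X)
    return model.fit()


# --------------------------------------------------------------------------
# fitting under MI
# --------------------------------------------------------------------------

def fit_full(stack: ImputedStack, spec: ModelSpec) -> FittedModel:
    """Per-imputation OLS with Rubin-pooled coefficients and averaged R²."""
    params, bses, r2s = [], [], []
    n_used = 0
    dfcom = None
    for df in stack.datasets:
        y, X = build_design(df, spec)
        _check_rank(X, spec.predictors)
        res = _ols(y, X)
        params.append(res.params)
        bses.append(res.bse)
        r2s.append(float(res.rsquared))
        n_used = len(y)
        dfcom = res.df_resid
    names = ["intercept"] + spec.predictors
    pooled = {
        name: pool_rubin([(p[j], b[j]) for p, b in zip(params, bses)], dfcom=dfcom)
        for j, name in enumerate(names)
    }
    perf = pool_performance(r2s)
    return FittedModel(
        spec=spec,
        intercept=pooled["intercept"],
        coefficients={n: pooled[n] for n in spec.predictors},
        n_used=n_used,
        r2_apparent=perf.mean,
        r2_per_imputation=perf.per_imputation,
    )


def fit_univariable(
    stack: ImputedStack, predictor: str, outcome: str, stratum: str = "pre"
) -> PooledEstimate:
    """Age-adjusted simple linear model; returns the pooled predictor slope."""
    if predictor == "age":
        raise ModelError("age is the adjustment variable, not a screened predictor")
    spec = ModelSpec(outcome, stratum, [predictor, "age"])
    for df in stack.datasets:
        sub = select_stratum(df, stratum)
        if sub[predictor].nunique(dropna=True) <= 1:
            raise ModelError(f"predictor {predictor!r} is constant")
    fitted = fit_full(stack, spec)
    return fitted.coefficients[predictor]


def backward_select(
    stack: ImputedStack, spec: ModelSpec, p_threshold: float = 0.05
) -> SelectionResult:
    """Pooled backward elimination at the given p threshold.

    Drops one predictor per step — the one with the largest Rubin-pooled
    p-value — until every remaining pooled p is below the threshold.  Age is
    eligible for removal like any other predictor; the menopause indicator is
    forced into combined-stratum models (it is the reason that model exists).
    Ties break toward the later column in spec order (deterministic).
    """
    if not spec.predictors:
        raise ModelError("backward selection needs at least one predictor")
    forced = {schema.MENOPAUSE_COLUMN} if spec.stratum == "combined" else set()
    current = list(spec.predictors)
    path: list[dict] = []
    fitted = None
    while current:
        fitted = fit_full(stack, spec.replace_predictors(current))
        pvals = {name: fitted.coefficients[name].p_value for name in current}
        removable = [n for n in current if n not in forced]
        if not removable:
            break
        worst = max(removable, key=lambda n: (pvals[n], current.index(n)))
        if pvals[worst] < p_threshold:
            break
        path.append({"dropped": worst, "pooled_p": pvals[worst],
                     "remaining": [c for c in current if c != worst]})
        current.remove(worst)
        fitted = None
    if current and fitted is None:
        fitted = fit_full(stack, spec.replace_predictors(current))
    if not current:
        fitted = None  # intercept-only
        logger.info("backward elimination removed every predictor (intercept-only)")
    return SelectionResult("backward", current, path, fitted)


# --------------------------------------------------------------------------
# stacked lasso
# --------------------------------------------------------------------------

def _stacked_arrays(stack: ImputedStack, spec: ModelSpec):
    """Stack m completed datasets; each participant gets total weight 1."""
    Xs, ys, groups = [], [], []
    for df in stack.datasets:
        sub = select_stratum(df, spec.stratum)
        X = sub[spec.predictors].to_numpy(dtype=float).copy()
        for j, c in enumerate(spec.predictors):
            X[:, j] *= spec.transforms.get(c, 1.0)
        Xs.append(X)
        ys.append(np.log(sub[spec.outcome_column].to_numpy(dtype=float)))
        groups.append(sub.index.to_numpy())
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    groups = np.concatenate(groups)
    w = np.full(len(y), 1.0 / stack.m)
    return X, y, w, groups


def _weighted_standardize(X, y, w):
    wn = w / w.sum()
    x_mean = wn @ X
    y_mean = float(wn @ y)
    Xc = X - x_mean
    x_sd = np.sqrt(wn @ (Xc**2))
    x_sd[x_sd == 0] = 1.0
    return Xc / x_sd, y - y_mean, x_mean, x_sd, y_mean


def lambda_max(X, y, w) -> float:
    """Smallest penalty at which every standardized coefficient is zero (KKT)."""
    Xs, yc, *_ = _weighted_standardize(X, y, w)
    wn = w / w.sum()
    return float(np.max(np.abs(Xs.T @ (wn * yc))))


def _solve_lasso(Xs, yc, w, lam) -> np.ndarray:
    """Weighted lasso on standardized, centered data.

    Rows are scaled by sqrt of the normalized weights so scikit-learn's
    coordinate descent minimizes exactly
    ``(1/2) * sum_i wn_i (y_i - x_i b)^2 + lam * ||b||_1``.
    """
    n = len(yc)
    sw = np.sqrt(w / w.sum() * n)
    Xw = Xs * sw[:, None]
    yw = yc * sw
    if lam <= 0:
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        return beta
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=50_000, tol=1e-10)
    model.fit(Xw, yw)
    return model.coef_


def default_lambda_grid(lmax: float, n_points: int = 60, ratio: float = 1e-3) -> np.ndarray:
    return lmax * np.logspace(0, np.log10(ratio), n_points)


def stacked_lasso(
    stack: ImputedStack,
    spec: ModelSpec,
    alpha: float = 1.0,
    lambda_grid: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Lasso over the stacked imputations with participant-grouped CV.

    Predictors are standardized with weighted means/SDs; the intercept is
    unpenalized (handled by centering).  All m copies of a participant land in
    the same CV fold.  The reported coefficients are on the original scale at
    the MSE-minimizing penalty.
    """
    if alpha != 1.0:
        raise ModelError("only the pure lasso (alpha = 1) is supported")
    X, y, w, groups = _stacked_arrays(stack, spec)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(lambda_max(X, y, w))
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ModelError("empty lambda grid")

    # participant-grouped fold assignment, seeded from the master seed
    rng = stage_rng(seed, "folds")
    unique_groups = np.unique(groups)
    fold_of_group = dict(
        zip(unique_groups, rng.permutation(len(unique_groups)) % n_folds)
    )
    fold = np.array([fold_of_group[g] for g in groups])

    cv_mse = np.zeros(lambda_grid.size)
    for f in range(n_folds):
        test = fold == f
        if not test.any() or test.all():
            continue
        Xs_tr, yc_tr, x_mean, x_sd, y_mean = _weighted_standardize(
            X[~test], y[~test], w[~test]
        )
        Xs_te = (X[test] - x_mean) / x_sd
        wn_te = w[test] / w[test].sum()
        for i, lam in enumerate(lambda_grid):
            beta = _solve_lasso(Xs_tr, yc_tr, w[~test], lam)
            resid = (y[test] - y_mean) - Xs_te @ beta
            cv_mse[i] += float(wn_te @ resid**2) * w[test].sum() / w.sum()

    best = int(np.argmin(cv_mse))
    lam_best = float(lambda_grid[best])

    Xs, yc, x_mean, x_sd, y_mean = _weighted_standardize(X, y, w)
    path = []
    for lam in lambda_grid:
        beta_std = _solve_lasso(Xs, yc, w, lam)
        path.append({"lambda": float(lam), "n_nonzero": int(np.sum(beta_std != 0))})
    beta_std = _solve_lasso(Xs, yc, w, lam_best)
    beta = beta_std / x_sd
    intercept = y_mean - float(x_mean @ beta)

    selected = [spec.predictors[j] for j in range(len(beta)) if beta_std[j] != 0.0]
    if not selected:
        logger.warning("lasso selected no predictors at the CV-chosen penalty")
    coef = {
        name: PooledEstimate(float(beta[j]), np.nan, np.nan, np.nan, np.inf,
                             np.nan, np.nan, stack.m)
        for j, name in enumerate(spec.predictors)
    }
    final = FittedModel(
        spec=spec,
        intercept=PooledEstimate(intercept, np.nan, np.nan, np.nan, np.inf,
                                 np.nan, np.nan, stack.m),
        coefficients=coef,
        n_used=len(np.unique(groups)),
        r2_apparent=float("nan"),
    )
    sel_path = [{"lambda_grid": [p["lambda"] for p in path],
                 "n_nonzero": [p["n_nonzero"] for p in path],
                 "cv_mse": cv_mse.tolist(),
                 "lambda_best": lam_best}]
    return SelectionResult("lasso", selected, sel_path, final)
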