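"""Synthetic cohort generator.

Emulates a random subcohort of midlife U.S. women with three serum iron
biomarkers (serum iron, ferritin, UIBC / transferrin saturation), a menopause
stratification, ~19 questionnaire predictors, and a missing-at-random
missingness mechanism.  The three outcomes are generated on the natural-log
scale as ``X @ beta + eps`` with stratum-specific coefficients and a
correlated trivariate residual; UIBC is derived algebraically from iron and
transferrin saturation so the saturation formula holds exactly.

The module also houses :func:`calibrate_generator`, the search that tunes the
free parameters (residual SDs, residual correlations, per-variable missing
rates) so that the simulated cohort reproduces a set of target summary
statistics (medians, prevalences, Spearman correlations, apparent R²).  The
packaged default configuration is the frozen output of that search.
"""
from __future__ import annotations

import logging
import math
from typing import Any, Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from . import schema
from ._rng import stage_rng
from .config import ConfigError, GeneratorConfig, OUTCOME_KEYS, STRATA

logger = logging.getLogger(__name__)

#: unit transforms applied when a covariate enters a linear predictor
#: (raw storage stays untouched): calcium is stored in mg, modeled in dg.
MODEL_TRANSFORMS = {"dietary_supp_calcium": 0.01}

_LN100 = math.log(100.0)
_OUT_ORDER = ("ferritin", "serum_iron", "transferrin_saturation")


class CalibrationError(RuntimeError):
    """Raised when the calibration search cannot reach its targets.

    Carries a ``report`` attribute with the best candidate and residuals.
    """

    def __init__(self, message: str, report: dict | None = None):
        super().__init__(message)
        self.report = report or {}


# --------------------------------------------------------------------------
# covariate sampling
# --------------------------------------------------------------------------

def _draw_marginal(rng: np.random.Generator, n: int, family: str, params: dict) -> np.ndarray:
    if family == "truncnorm":
        loc, scale = params["loc"], params["scale"]
        a = (params.get("lower", -np.inf) - loc) / scale
        b = (params.get("upper", np.inf) - loc) / scale
        return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    if family == "lognormal":
        mu, s = math.log(params["median"]), params["sigma_log"]
        hi = params.get("upper")
        b = (math.log(hi) - mu) / s if hi else np.inf
        z = stats.truncnorm.rvs(-np.inf, b, size=n, random_state=rng)
        return np.exp(mu + s * z)
    if family == "bernoulli":
        return (rng.random(n) < params["p"]).astype(float)
    raise ConfigError(f"cannot draw family {family!r}")


def _draw_covariates(
    rng: np.random.Generator, n: int, stratum: str, config: GeneratorConfig
) -> pd.DataFrame:
    """Draw one stratum's covariate block (structural missings included)."""
    out: dict[str, np.ndarray] = {}
    derived: list[str] = []
    for name, spec in config.covariates.items():
        family = spec["family"]
        post_only = spec.get("post_only", False)
        if post_only and stratum == "pre":
            out[name] = np.full(n, np.nan)
            continue
        if family == "derived":
            derived.append(name)
            continue
        out[name] = _draw_marginal(rng, n, family, config.stratum_params(name, stratum))

    if stratum == "post" and derived:
        out.update(_derive_reproductive(rng, n, out["age"], config.menopause_link, derived))
    elif derived:
        for name in derived:
            out[name] = np.full(n, np.nan)

    df = pd.DataFrame(out)
    df[schema.MENOPAUSE_COLUMN] = 1.0 if stratum == "post" else 0.0
    return df


def _derive_reproductive(
    rng: np.random.Generator,
    n: int,
    age: np.ndarray,
    link: dict[str, float],
    names: list[str],
) -> dict[str, np.ndarray]:
    """Age-linked reproductive history for postmenopausal rows.

    Age at menopause is truncated-normal below each woman's current age, so
    years-since-LMP is positive by construction and correlates with age;
    reproductive lifespan subtracts an age at menarche drawn around 13 y.
    """
    loc, scale = link["age_menopause_mean"], link["age_menopause_sd"]
    lower = link.get("age_menopause_lower", 30.0)
    upper = np.minimum(link.get("age_menopause_upper", 58.0), age - link.get("min_years_since", 0.5))
    a = (lower - loc) / scale
    b = (upper - loc) / scale
    age_menopause = stats.truncnorm.rvs(a, np.maximum(b, a + 1e-6), loc=loc, scale=scale,
                                        size=n, random_state=rng)
    m_loc, m_scale = link["menarche_mean"], link["menarche_sd"]
    menarche = stats.truncnorm.rvs(
        (link.get("menarche_lower", 9.0) - m_loc) / m_scale,
        (link.get("menarche_upper", 18.0) - m_loc) / m_scale,
        loc=m_loc, scale=m_scale, size=n, random_state=rng,
    )
    values = {
        "years_since_lmp": age - age_menopause,
        "reproductive_lifespan": age_menopause - menarche,
    }
    return {name: values[name] for name in names}


# --------------------------------------------------------------------------
# outcome generation
# --------------------------------------------------------------------------

def _linear_predictor(cov: pd.DataFrame, coef_map: dict[str, float]) -> np.ndarray:
    eta = np.zeros(len(cov))
    for key, beta in coef_map.items():
        if key not in cov.columns:
            raise ConfigError(f"coefficient key {key!r} names no generated column")
        scale = MODEL_TRANSFORMS.get(key, 1.0)
        eta += beta * scale * cov[key].to_numpy()
    return eta


def _residual_cholesky(config: GeneratorConfig, stratum: str) -> np.ndarray:
    sds = np.array([config.sigma[o][stratum] for o in _OUT_ORDER])
    cov = config.residual_corr_matrix() * np.outer(sds, sds)
    return np.linalg.cholesky(cov)


def _draw_outcomes(
    rng: np.random.Generator, cov: pd.DataFrame, stratum: str, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Return (outcome block, true ln-scale linear predictors, intercepts)."""
    n = len(cov)
    etas = np.column_stack(
        [_linear_predictor(cov, config.betas[o][stratum]) for o in _OUT_ORDER]
    )
    L = _residual_cholesky(config, stratum)
    eps = rng.standard_normal((n, 3)) @ L.T
    # center each outcome so the realized stratum median hits its target; the
    # centering uses eta + eps (not eta alone) because the skewed linear
    # predictor shifts the median of the convolution
    intercepts = {}
    for j, outcome in enumerate(_OUT_ORDER):
        icept = math.log(config.outcome_medians[outcome][stratum]) - float(
            np.median(etas[:, j] + eps[:, j])
        )
        intercepts[outcome] = icept
    mu = etas + np.array([intercepts[o] for o in _OUT_ORDER])
    ln_out = mu + eps
    # transferrin saturation is a percentage: resample the residual triple for
    # rows that would exceed 100% (truncation keeps the residual correlation).
    for _ in range(200):
        bad = ln_out[:, 2] >= _LN100
        if not bad.any():
            break
        ln_out[bad] = mu[bad] + rng.standard_normal((int(bad.sum()), 3)) @ L.T
    assert (ln_out[:, 2] < _LN100).all(), "saturation truncation failed to converge"

    ferritin = np.exp(ln_out[:, 0])
    iron = np.exp(ln_out[:, 1])
    ts = np.exp(ln_out[:, 2])
    assert (ferritin > 0).all() and (iron > 0).all() and (ts > 0).all()
    uibc = iron * (100.0 - ts) / ts

    block = pd.DataFrame(
        {"serum_iron": iron, "ferritin": ferritin, "uibc": uibc, "transferrin_saturation": ts}
    )
    truth = pd.DataFrame({"ln_ferritin": mu[:, 0], "ln_iron": mu[:, 1], "ln_ts": mu[:, 2]})
    return block, truth, intercepts


def generate_cohort(
    config: GeneratorConfig, return_truth: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, Any]]:
    """Generate a complete cohort (no missing values beyond structural ones).

    Deterministic given ``config.seed``.  With ``return_truth=True`` also
    returns the generating model's ln-scale linear predictors and intercepts,
    which serve as oracles in tests and calibration checks.
    """
    config.validate()
    rng_cov = stage_rng(config.seed, "covariates")
    rng_out = stage_rng(config.seed, "outcomes")

    frames, truths = [], []
    intercepts: dict[str, dict[str, float]] = {o: {} for o in _OUT_ORDER}
    for stratum, n in (("pre", config.n_pre), ("post", config.n_post)):
        if n == 0:
            continue
        cov = _draw_covariates(rng_cov, n, stratum, config)
        block, truth, icepts = _draw_outcomes(rng_out, cov, stratum, config)
        for o, v in icepts.items():
            intercepts[o][stratum] = v
        frames.append(pd.concat([cov, block], axis=1))
        truths.append(truth)

    df = pd.concat(frames, ignore_index=True)
    truth_df = pd.concat(truths, ignore_index=True)
    perm = rng_cov.permutation(len(df))
    df = df.iloc[perm].reset_index(drop=True)
    truth_df = truth_df.iloc[perm].reset_index(drop=True)
    df.insert(0, schema.ID_COLUMN, np.arange(1, len(df) + 1))
    df = df[[c for c in schema.ALL_COLUMNS if c in df.columns]]
    if return_truth:
        return df, {"linpred": truth_df, "intercepts": intercepts}
    return df


# --------------------------------------------------------------------------
# missingness
# --------------------------------------------------------------------------

def _split_count(total: int, n_pre: int, n_post: int) -> tuple[int, int]:
    """Largest-remainder proportional split of ``total`` across strata."""
    share_pre = total * n_pre / (n_pre + n_post)
    k_pre = int(round(share_pre))
    return k_pre, total - k_pre


def _solve_logistic_intercept(z: np.ndarray, rate: float) -> float:
    """Intercept a with mean(expit(a + z)) == rate on the realized scores."""
    if rate <= 0.0:
        return -np.inf
    if rate >= 1.0:
        return np.inf
    f = lambda a: float(np.mean(expit(a + z))) - rate
    return optimize.brentq(f, -30.0, 30.0)


def _mar_scores(df: pd.DataFrame, dependence: dict[str, float], exclude: str | None) -> np.ndarray:
    z = np.zeros(len(df))
    for var, slope in dependence.items():
        if var == exclude:
            continue
        x = df[var].to_numpy(dtype=float)
        sd = np.nanstd(x)
        if sd > 0:
            z += slope * (x - np.nanmean(x)) / sd
    return z


def impose_missingness(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Blank cells of a complete cohort under the configured MAR mechanism.

    Each variable's missingness indicator follows a logistic model on
    standardized age and BMI (MAR by construction: the mechanism never reads
    the value it deletes).  Additionally blanks all three serum markers for
    ``n_all_missing_outcomes`` rows (split across strata proportionally) and
    the menopause indicator for ``n_menopause_missing`` rows.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    df = cohort.copy()
    rng = stage_rng(config.seed, "missingness")
    meno = df[schema.MENOPAUSE_COLUMN]

    # --- rows with every serum marker missing (the exclusion-filter rows)
    k_pre, k_post = _split_count(config.n_all_missing_outcomes, config.n_pre, config.n_post)
    all_missing_idx: list[np.ndarray] = []
    for stratum_val, k in ((0.0, k_pre), (1.0, k_post)):
        pool = df.index[meno == stratum_val].to_numpy()
        k = min(k, len(pool))
        if k > 0:
            all_missing_idx.append(rng.choice(pool, size=k, replace=False))
    excl = np.concatenate(all_missing_idx) if all_missing_idx else np.array([], dtype=int)
    df.loc[excl, schema.OUTCOME_COLUMNS] = np.nan

    # --- rows with unknown menopause status (kept out of stratified analyses)
    m_pre, m_post = _split_count(config.n_menopause_missing, config.n_pre, config.n_post)
    for stratum_val, k in ((0.0, m_pre), (1.0, m_post)):
        pool = np.setdiff1d(df.index[meno == stratum_val].to_numpy(), excl)
        if k > 0 and len(pool) > 0:
            chosen = rng.choice(pool, size=min(k, len(pool)), replace=False)
            df.loc[chosen, schema.MENOPAUSE_COLUMN] = np.nan

    dependence = config.missingness.get("dependence", {})

    # --- serum marker MAR (on rows not already fully blanked)
    remaining = np.setdiff1d(df.index.to_numpy(), excl)
    for marker, rate in config.missingness.get("outcome_rates", {}).items():
        if rate <= 0:
            continue
        z = _mar_scores(cohort.loc[remaining], dependence, exclude=None)
        a = _solve_logistic_intercept(z, rate)
        mask = rng.random(len(remaining)) < expit(a + z)
        df.loc[remaining[mask], marker] = np.nan
    # saturation is a derived quantity: undefined whenever iron or UIBC is
    df.loc[df["serum_iron"].isna() | df["uibc"].isna(), "transferrin_saturation"] = np.nan

    # --- predictor MAR, per stratum
    for var, per_stratum in config.missingness.get("predictor_rates", {}).items():
        post_only = config.covariates[var].get("post_only", False)
        for stratum, rate in per_stratum.items():
            if rate <= 0:
                continue
            if post_only and stratum == "pre":
                continue
            rows = df.index[meno == (1.0 if stratum == "post" else 0.0)].to_numpy()
            if len(rows) == 0:
                continue
            z = _mar_scores(cohort.loc[rows], dependence, exclude=var)
            a = _solve_logistic_intercept(z, rate)
            mask = rng.random(len(rows)) < expit(a + z)
            df.loc[rows[mask], var] = np.nan
    return df


def model_variables(stratum: str) -> list[str]:
    """The multivariable-model variable set for a stratum."""
    return list(schema.PREDICTORS_BY_STRATUM[stratum])


def any_missing_fraction(cohort: pd.DataFrame, stratum: str) -> float:
    """Fraction of a stratum's rows with >= 1 missing model variable."""
    meno_val = 1.0 if stratum == "post" else 0.0
    sub = cohort[cohort[schema.MENOPAUSE_COLUMN] == meno_val]
    cols = [c for c in model_variables(stratum) if c != schema.MENOPAUSE_COLUMN]
    return float(sub[cols].isna().any(axis=1).mean())


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def _analysis_sizes(config: GeneratorConfig) -> dict[str, int]:
    """Post-exclusion stratum sizes implied by the configuration."""
    k_pre, k_post = _split_count(config.n_all_missing_outcomes, config.n_pre, config.n_post)
    m_pre, m_post = _split_count(config.n_menopause_missing, config.n_pre, config.n_post)
    n_pre = config.n_pre - k_pre - m_pre
    n_post = config.n_post - k_post - m_post
    return {"pre": n_pre, "post": n_post, "combined": n_pre + n_post}


def _apparent_from_population(r2_pop: float, p: int, n: int) -> float:
    """Expected apparent R² of OLS at sample size n with p regressors."""
    return r2_pop + (1.0 - r2_pop) * p / (n - 1)


def _population_from_apparent(r2_app: float, p: int, n: int) -> float:
    shrink = p / (n - 1)
    return (r2_app - shrink) / (1.0 - shrink)


class _McDesign:
    """Large Monte-Carlo covariate draw used by the calibration solvers."""

    def __init__(self, config: GeneratorConfig, n_mc: int, seed: int):
        rng = stage_rng(seed, "calibration")
        self.config = config
        self.n_mc = n_mc
        self.cov = {s: _draw_covariates(rng, n_mc, s, config) for s in STRATA}
        self.z = {s: rng.standard_normal((n_mc, 3)) for s in STRATA}
        self.eta = {
            s: {
                o: _linear_predictor(self.cov[s], config.betas[o][s])
                for o in OUTCOME_KEYS
            }
            for s in STRATA
        }

    def explained_var(self, outcome: str, stratum: str) -> float:
        return float(np.var(self.eta[stratum][outcome]))

    def linpred(self, outcome: str, stratum: str, config: GeneratorConfig) -> np.ndarray:
        # mirrors the generator's centering: the intercept offsets the median
        # of eta + eps at the configured residual SD
        eta = self.eta[stratum][outcome]
        j = _OUT_ORDER.index(outcome)
        noise = config.sigma[outcome][stratum] * self.z[stratum][:, j]
        icept = math.log(config.outcome_medians[outcome][stratum]) - float(
            np.median(eta + noise)
        )
        return icept + eta

    def combined_projection(self, outcome: str, config: GeneratorConfig) -> tuple[float, float]:
        """(explained, structural-unexplained) variance of the combined model.

        Regresses the noise-free combined linear predictor on the combined
        design (common predictors + menopause); the residual variance is the
        part of the mean structure the common-coefficient model cannot carry
        (stratum-specific coefficients and post-only variables).
        """
        cols = [c for c in schema.PREDICTORS_BY_STRATUM["combined"]]
        X_parts, y_parts = [], []
        for s in STRATA:
            block = self.cov[s][cols].to_numpy(dtype=float)
            X_parts.append(block)
            y_parts.append(self.linpred(outcome, s, config))
        X = np.vstack(X_parts)
        X = np.column_stack([np.ones(len(X)), X])
        y = np.concatenate(y_parts)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        return float(np.var(fitted)), float(np.var(y - fitted))


def _simulate_outcomes_mc(mc: _McDesign, config: GeneratorConfig) -> pd.DataFrame:
    """Noise-added ln outcomes over the MC design (fixed normal draws).

    Applies the same saturation-below-100% truncation resampling as the
    generator, so correlation calibration targets what the generator emits.
    """
    frames = []
    redraw_rng = np.random.default_rng(987_654_321)  # fixed: calibration determinism
    for s in STRATA:
        mu = np.column_stack([mc.linpred(o, s, config) for o in _OUT_ORDER])
        L = _residual_cholesky(config, s)
        ln_out = mu + mc.z[s] @ L.T
        for _ in range(200):
            bad = ln_out[:, 2] >= _LN100
            if not bad.any():
                break
            ln_out[bad] = mu[bad] + redraw_rng.standard_normal((int(bad.sum()), 3)) @ L.T
        frames.append(pd.DataFrame(ln_out, columns=list(_OUT_ORDER)))
    return pd.concat(frames, ignore_index=True)


def _set_sigma(config: GeneratorConfig, outcome: str, stratum: str, value: float) -> None:
    config.sigma[outcome][stratum] = float(value)


_SPEARMAN_PAIRS = {
    ("serum_iron", "transferrin_saturation"): "iron_ts",
    ("ferritin", "serum_iron"): "ferritin_iron",
    ("ferritin", "transferrin_saturation"): "ferritin_ts",
}


def calibrate_generator(
    targets: dict[str, float],
    base_config: GeneratorConfig | None = None,
    n_mc: int = 100_000,
    sigma_cap: float = 0.60,
    max_iter: int = 8,
    tolerances: dict[str, float] | None = None,
    pipeline_refinement: int = 0,
) -> GeneratorConfig:
    """Tune free generator parameters to hit target summary statistics.

    ``targets`` maps colon-separated keys to values:

    - ``prevalence:<var>:<stratum|all>`` — Bernoulli p (set directly)
    - ``median:<var>:<stratum>`` — location of a symmetric family or the
      median of a lognormal (set directly)
    - ``outcome_median:<outcome>:<stratum>`` — target outcome median
    - ``population_r2:<outcome>:<stratum>`` — residual SD solved from
      R² = Var(X beta) / (Var(X beta) + sigma²) with a Monte-Carlo Var(X beta)
    - ``apparent_r2:<outcome>:<pre|post|combined>`` — residual SDs solved
      jointly (least squares for ferritin when a combined target is present)
      with a finite-sample optimism adjustment at the analysis sample size;
      iron/TS solutions are capped at ``sigma_cap`` to keep the generated
      markers physiologic (saturation < 100%)
    - ``spearman:<outcome_a>:<outcome_b>`` — residual correlations solved by
      a damped simulation fixed point against the combined-sample Spearman
    - ``any_missing:<stratum>`` — per-variable missing rates scaled so the
      fraction of rows with >= 1 missing model variable hits the target

    Raises :class:`CalibrationError` (with a diagnostic report) if the final
    verification misses a target by more than three tolerances.
    """
    cfg = (base_config or GeneratorConfig.default()).replace()
    tol = {
        "prevalence": 0.01, "median": 0.02, "outcome_median": 0.02,
        "population_r2": 0.02, "apparent_r2": 0.035, "spearman": 0.03,
        "any_missing": 0.025,
    }
    tol.update(tolerances or {})

    # ---- direct-set targets
    for key, value in targets.items():
        kind, *parts = key.split(":")
        if kind == "prevalence":
            var, stratum = parts
            strata = STRATA if stratum == "all" else (stratum,)
            if cfg.covariates[var]["family"] != "bernoulli":
                raise CalibrationError(f"{var!r} is not a Bernoulli covariate")
            for s in strata:
                cfg.covariates[var][s]["p"] = float(value)
        elif kind == "median":
            var, stratum = parts
            fam = cfg.covariates[var]["family"]
            params = cfg.stratum_params(var, stratum)
            if fam == "truncnorm":
                params["loc"] = float(value)
            elif fam == "lognormal":
                params["median"] = float(value)
            else:
                raise CalibrationError(f"median target unsupported for family {fam!r}")
        elif kind == "outcome_median":
            outcome, stratum = parts
            cfg.outcome_medians[outcome][stratum] = float(value)

    mc = _McDesign(cfg, n_mc, cfg.seed)
    sizes = _analysis_sizes(cfg)
    p_by_stratum = {s: len(schema.PREDICTORS_BY_STRATUM[s]) for s in ("pre", "post", "combined")}

    # ---- population-R² targets (closed form via MC explained variance)
    for key, value in targets.items():
        if key.startswith("population_r2:"):
            _, outcome, stratum = key.split(":")
            ve = mc.explained_var(outcome, stratum)
            _set_sigma(cfg, outcome, stratum, math.sqrt(ve * (1.0 - value) / value))

    # ---- apparent-R² targets
    app = {k.split(":", 1)[1]: v for k, v in targets.items() if k.startswith("apparent_r2:")}
    capped: set[str] = set()
    for outcome in ("serum_iron", "transferrin_saturation"):
        for stratum in STRATA:
            t = app.get(f"{outcome}:{stratum}")
            if t is None:
                continue
            pop = _population_from_apparent(t, p_by_stratum[stratum], sizes[stratum])
            ve = mc.explained_var(outcome, stratum)
            sigma = math.sqrt(ve * (1.0 - pop) / pop)
            if sigma > sigma_cap:
                capped.add(f"apparent_r2:{outcome}:{stratum}")
            _set_sigma(cfg, outcome, stratum, min(sigma, sigma_cap))

    ferr_targets = {s: app.get(f"ferritin:{s}") for s in ("pre", "post", "combined")}
    if any(v is not None for v in ferr_targets.values()):
        _solve_ferritin_sigmas(cfg, mc, ferr_targets, sizes, p_by_stratum)
        if pipeline_refinement > 0:
            # the analytic solve targets complete-data apparent R²; the MI
            # pipeline (impute, fit per imputation, average) measures the same
            # quantity with a small offset (imputation models borrow outcome
            # information).  Measure that offset and re-solve against
            # offset-adjusted targets so the calibration matches the
            # statistic the pipeline reports.
            offsets = _mi_apparent_offsets(cfg, mc, ferr_targets, sizes,
                                           p_by_stratum, pipeline_refinement)
            adj = {s: (t - offsets.get(s, 0.0)) if t is not None else None
                   for s, t in ferr_targets.items()}
            _solve_ferritin_sigmas(cfg, mc, adj, sizes, p_by_stratum)

    # ---- Spearman targets (residual correlations, simulation fixed point)
    spearman_targets = {}
    for key, value in targets.items():
        if key.startswith("spearman:"):
            _, a, b = key.split(":")
            pair = _SPEARMAN_PAIRS.get((a, b)) or _SPEARMAN_PAIRS.get((b, a))
            if pair is None:
                raise CalibrationError(f"unknown Spearman pair {key!r}")
            spearman_targets[pair] = float(value)
    if spearman_targets:
        _solve_residual_corr(cfg, mc, spearman_targets, max_iter)

    # ---- missingness scale
    for stratum in STRATA:
        t = targets.get(f"any_missing:{stratum}")
        if t is not None:
            _solve_missing_scale(cfg, mc, stratum, t)

    # ---- verification; targets whose sigma solve hit the physiologic cap are
    # reported but cannot fail the search (they are unreachable by design)
    report = _verification_report(cfg, targets, tol)
    report["sigma_capped"] = sorted(capped)
    cfg.calibration = report
    worst = max(
        (r["excess"] for k, r in report["residuals"].items() if k not in capped),
        default=0.0,
    )
    if worst > 3.0:
        raise CalibrationError(
            f"calibration verification off by {worst:.1f}x tolerance", report
        )
    return cfg


def _solve_ferritin_sigmas(cfg, mc, ferr_targets, sizes, p_by_stratum,
                           tol: float = 0.03) -> None:
    """Joint minimax solve of the two ferritin residual SDs.

    The pre/post/combined apparent R² are three targets for two free
    parameters; under the published coefficients they cannot all be met
    exactly, so the solution minimizes the maximum tolerance-normalized
    deviation (the calibration's contract is "within the stated tolerance",
    which makes the Chebyshev criterion the natural objective; each target
    lands within ~0.025 under the packaged defaults).
    """
    ve = {s: mc.explained_var("ferritin", s) for s in STRATA}
    w_post = sizes["post"] / sizes["combined"]
    w = {"pre": 1.0 - w_post, "post": w_post}
    want_comb = ferr_targets.get("combined")
    if want_comb is not None:
        v_proj, v_struct = mc.combined_projection("ferritin", cfg)

    def apparent(log_sigmas: np.ndarray) -> dict[str, float]:
        sig = {s: math.exp(log_sigmas[i]) for i, s in enumerate(STRATA)}
        out = {}
        for s in STRATA:
            pop = ve[s] / (ve[s] + sig[s] ** 2)
            out[s] = _apparent_from_population(pop, p_by_stratum[s], sizes[s])
        if want_comb is not None:
            noise = sum(w[s] * sig[s] ** 2 for s in STRATA)
            pop_c = v_proj / (v_proj + v_struct + noise)
            out["combined"] = _apparent_from_population(
                pop_c, p_by_stratum["combined"], sizes["combined"]
            )
        return out

    keys = [s for s in ("pre", "post", "combined") if ferr_targets.get(s) is not None]

    def worst_dev(log_sigmas: np.ndarray) -> float:
        a = apparent(log_sigmas)
        return max(abs(a[k] - ferr_targets[k]) / tol for k in keys)

    x0 = np.log([cfg.sigma["ferritin"]["pre"], cfg.sigma["ferritin"]["post"]])
    sol = optimize.minimize(worst_dev, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    for i, s in enumerate(STRATA):
        _set_sigma(cfg, "ferritin", s, math.exp(sol.x[i]))


def _mi_apparent_offsets(cfg, mc, ferr_targets, sizes, p_by_stratum,
                         n_seeds: int) -> dict[str, float]:
    """Mean (MI-pipeline minus analytic) apparent-R² offset per stratum."""
    from .mi import impute  # local: avoid an import cycle
    from .models import ModelSpec, fit_full
    from .preprocess import exclude_all_missing_outcomes

    strata = [s for s, t in ferr_targets.items() if t is not None]
    analytic = _ferritin_analytic_apparent(cfg, mc, sizes, p_by_stratum)
    mi_vals: dict[str, list[float]] = {s: [] for s in strata}
    for k in range(n_seeds):
        c = cfg.replace(seed=int(stage_rng(cfg.seed, "calibration", 1 + k).integers(2**31 - 1)))
        analyzed = exclude_all_missing_outcomes(impose_missingness(generate_cohort(c), c))
        stack = impute(analyzed, m=5, n_iter=10, seed=c.seed)
        for s in strata:
            mi_vals[s].append(fit_full(stack, ModelSpec("ln_ferritin", s)).r2_apparent)
    return {s: float(np.mean(mi_vals[s])) - analytic[s] for s in strata}


def _ferritin_analytic_apparent(cfg, mc, sizes, p_by_stratum) -> dict[str, float]:
    ve = {s: mc.explained_var("ferritin", s) for s in STRATA}
    out = {}
    for s in STRATA:
        pop = ve[s] / (ve[s] + cfg.sigma["ferritin"][s] ** 2)
        out[s] = _apparent_from_population(pop, p_by_stratum[s], sizes[s])
    v_proj, v_struct = mc.combined_projection("ferritin", cfg)
    w_post = sizes["post"] / sizes["combined"]
    noise = w_post * cfg.sigma["ferritin"]["post"] ** 2 + (1 - w_post) * cfg.sigma["ferritin"]["pre"] ** 2
    pop_c = v_proj / (v_proj + v_struct + noise)
    out["combined"] = _apparent_from_population(pop_c, p_by_stratum["combined"], sizes["combined"])
    return out


def _solve_residual_corr(cfg, mc, targets: dict[str, float], max_iter: int) -> None:
    idx = {"ferritin": 0, "serum_iron": 1, "transferrin_saturation": 2}
    pair_cols = {
        "iron_ts": ("serum_iron", "transferrin_saturation"),
        "ferritin_iron": ("ferritin", "serum_iron"),
        "ferritin_ts": ("ferritin", "transferrin_saturation"),
    }
    for _ in range(max_iter):
        sim = _simulate_outcomes_mc(mc, cfg)
        sds = sim.std()
        max_err = 0.0
        for pair, target in targets.items():
            a, b = pair_cols[pair]
            s_now = float(stats.spearmanr(sim[a], sim[b]).statistic)
            err = target - s_now
            max_err = max(max_err, abs(err))
            # damped Newton step; the sensitivity of the total Spearman to the
            # residual correlation is ~ sigma_a*sigma_b/(sd_a*sd_b)
            sig_a = np.sqrt(np.mean([cfg.sigma[a][s] ** 2 for s in STRATA]))
            sig_b = np.sqrt(np.mean([cfg.sigma[b][s] ** 2 for s in STRATA]))
            gain = (sds[a] * sds[b]) / (sig_a * sig_b)
            cfg.residual_corr[pair] = float(
                np.clip(cfg.residual_corr[pair] + 0.9 * err * gain, -0.995, 0.995)
            )
        # keep the correlation matrix positive definite
        while np.linalg.eigvalsh(cfg.residual_corr_matrix()).min() <= 1e-6:
            for pair in cfg.residual_corr:
                cfg.residual_corr[pair] *= 0.98
        if max_err < 0.004:
            break


def _solve_missing_scale(cfg, mc, stratum: str, target: float) -> None:
    """Scale the stratum's per-variable rates so P(>= 1 missing) == target."""
    cap = cfg.missingness.get("rate_caps", {}).get(stratum, 1.0)
    dependence = cfg.missingness.get("dependence", {})
    cov = mc.cov[stratum]
    base = {
        var: rates[stratum]
        for var, rates in cfg.missingness["predictor_rates"].items()
        if not (cfg.covariates[var].get("post_only", False) and stratum == "pre")
        and rates.get(stratum, 0.0) > 0.0
        and var in schema.PREDICTORS_BY_STRATUM[stratum]
    }
    if not base:
        return
    scores = {var: _mar_scores(cov, dependence, exclude=var) for var in base}

    def any_missing_prob(scale: float) -> float:
        p_obs = np.ones(len(cov))
        for var, rate in base.items():
            r = min(rate * scale, cap)
            a = _solve_logistic_intercept(scores[var], r)
            p_obs *= 1.0 - expit(a + scores[var])
        return float(1.0 - p_obs.mean())

    lo, hi = 1e-3, 50.0
    if any_missing_prob(hi) < target:
        scale = hi
    else:
        scale = optimize.brentq(lambda s: any_missing_prob(s) - target, lo, hi, xtol=1e-4)
    for var in base:
        cfg.missingness["predictor_rates"][var][stratum] = float(min(base[var] * scale, cap))


def _verification_report(cfg: GeneratorConfig, targets: dict[str, float],
                         tol: dict[str, float]) -> dict:
    """Simulate one full default-size cohort and measure every target."""
    from .preprocess import exclude_all_missing_outcomes  # local import: no cycle

    complete = generate_cohort(cfg)
    observed = impose_missingness(complete, cfg)
    analyzed = exclude_all_missing_outcomes(observed)

    achieved: dict[str, float] = {}
    for key, target in targets.items():
        kind, *parts = key.split(":")
        if kind == "prevalence":
            var, stratum = parts
            if stratum == "all":
                achieved[key] = float(analyzed[var].mean())
            else:
                meno = 1.0 if stratum == "post" else 0.0
                achieved[key] = float(
                    analyzed.loc[analyzed[schema.MENOPAUSE_COLUMN] == meno, var].mean()
                )
        elif kind in ("median", "outcome_median"):
            var, stratum = parts
            meno = 1.0 if stratum == "post" else 0.0
            achieved[key] = float(
                analyzed.loc[analyzed[schema.MENOPAUSE_COLUMN] == meno, var].median()
            )
        elif kind == "spearman":
            a, b = parts
            sub = analyzed[[a, b]].dropna()
            achieved[key] = float(stats.spearmanr(sub[a], sub[b]).statistic)
        elif kind == "any_missing":
            achieved[key] = any_missing_fraction(observed, parts[0])
        elif kind in ("apparent_r2", "population_r2"):
            outcome, stratum = parts
            measured = _apparent_r2_complete(complete, cfg, outcome, stratum)
            if kind == "population_r2":
                # back out the finite-sample optimism so the population-scale
                # target is compared on its own scale
                p = len(schema.PREDICTORS_BY_STRATUM[stratum])
                n_s = int((complete[schema.MENOPAUSE_COLUMN] == (1.0 if stratum == "post" else 0.0)).sum()) \
                    if stratum != "combined" else len(complete)
                measured = _population_from_apparent(measured, p, max(n_s, p + 2))
            achieved[key] = measured

    residuals = {}
    for key, target in targets.items():
        kind = key.split(":")[0]
        got = achieved.get(key, np.nan)
        if kind in ("median", "outcome_median"):
            err = abs(got / target - 1.0) if target else abs(got)
        else:
            err = abs(got - target)
        residuals[key] = {
            "target": target,
            "achieved": got,
            "abs_error": err,
            "excess": float(err / tol.get(kind, 0.05)),
        }
    return {"targets": dict(targets), "achieved": achieved, "residuals": residuals,
            "sigma": {o: dict(v) for o, v in cfg.sigma.items()},
            "residual_corr": dict(cfg.residual_corr)}


def _apparent_r2_complete(complete: pd.DataFrame, cfg: GeneratorConfig,
                          outcome: str, stratum: str) -> float:
    """Apparent R² of the full OLS model on the pre-missingness cohort."""
    if stratum == "combined":
        sub = complete
    else:
        meno = 1.0 if stratum == "post" else 0.0
        sub = complete[complete[schema.MENOPAUSE_COLUMN] == meno]
    cols = schema.PREDICTORS_BY_STRATUM[stratum]
    X = sub[cols].to_numpy(dtype=float).copy()
    for j, c in enumerate(cols):
        X[:, j] *= MODEL_TRANSFORMS.get(c, 1.0)
    X = np.column_stack([np.ones(len(X)), X])
    y = np.log(sub[schema.OUTCOME_COLUMN_BY_KEY[outcome]].to_numpy(dtype=float))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(1.0 - resid.var() / y.var())
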