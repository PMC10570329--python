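"""Generator configuration: the full parameterization of the synthetic cohort.

The configuration carries everything the generator needs — stratum sizes,
per-covariate marginal distributions, the linear coefficient maps for the
three ln-scale outcomes, residual SDs and residual correlations, and the
missing-data mechanism.  The packaged default (``data/defaults.yaml``) is the
output of the calibration search in :func:`ironpred.generate.calibrate_generator`
and reproduces the published cohort's summary statistics; see
``docs/methods.md`` for what is and is not emulated.
"""
from __future__ import annotations

import copy
import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from . import schema


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


STRATA = ("pre", "post")
OUTCOME_KEYS = ("ferritin", "serum_iron", "transferrin_saturation")
RESIDUAL_CORR_KEYS = ("iron_ts", "ferritin_iron", "ferritin_ts")
FAMILIES = ("truncnorm", "lognormal", "bernoulli", "derived")


@dataclass
class GeneratorConfig:
    """Parameter bundle for :func:`ironpred.generate.generate_cohort`.

    Attributes
    ----------
    n_pre, n_post
        Stratum sizes generated (before any exclusions).
    n_menopause_missing
        Rows whose menopause indicator is blanked by the missingness stage.
    n_all_missing_outcomes
        Rows whose three serum markers are all blanked (the exclusion-filter
        fodder).
    covariates
        name -> ``{"family": ..., "post_only": bool, "pre": {...}, "post": {...}}``.
        Families: ``truncnorm`` (loc/scale/lower/upper), ``lognormal``
        (median/sigma_log, optional upper bound), ``bernoulli`` (p),
        ``derived`` (built from the menopause link, e.g. years since LMP).
    menopause_link
        Parameters tying age, age at menopause and age at menarche together
        for the derived reproductive variables.
    outcome_medians
        outcome key -> stratum -> target median on the natural scale; the
        generator centers each stratum's linear predictor so the realized
        median matches.
    betas
        outcome key -> stratum -> {covariate: coefficient} on the ln-outcome
        scale (calcium per decigram).
    sigma
        outcome key -> stratum -> residual SD on the ln scale.
    residual_corr
        Correlations of the trivariate residual (ferritin, iron, TS errors).
    missingness
        ``dependence`` (logistic slopes on standardized age/BMI),
        ``predictor_rates`` (var -> stratum -> marginal rate) and
        ``outcome_rates`` (serum marker -> rate).
    seed
        Master seed; stage streams are spawned from it (see ``_rng``).
    """

    seed: int
    n_pre: int
    n_post: int
    n_menopause_missing: int
    n_all_missing_outcomes: int
    covariates: dict[str, dict[str, Any]]
    menopause_link: dict[str, float]
    outcome_medians: dict[str, dict[str, float]]
    betas: dict[str, dict[str, dict[str, float]]]
    sigma: dict[str, dict[str, float]]
    residual_corr: dict[str, float]
    missingness: dict[str, Any]
    calibration: dict[str, Any] | None = field(default=None, repr=False)

    # ------------------------------------------------------------------ io
    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d.get("calibration") is None:
            d.pop("calibration", None)
        return d

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def default(cls) -> "GeneratorConfig":
        """The packaged, calibration-frozen default configuration."""
        ref = importlib.resources.files("ironpred.data").joinpath("defaults.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))

    def replace(self, **kwargs) -> "GeneratorConfig":
        """A validated copy with fields swapped.

        The copy is deep: the nested parameter dicts are never shared with
        the source, so mutating one configuration (e.g. during calibration)
        cannot alias another.
        """
        cfg = dataclasses.replace(copy.deepcopy(self), **kwargs)
        cfg.validate()
        return cfg

    # ------------------------------------------------------------ helpers
    @property
    def n_total(self) -> int:
        return self.n_pre + self.n_post

    def stratum_params(self, name: str, stratum: str) -> dict[str, Any]:
        spec = self.covariates[name]
        params = spec.get(stratum)
        if params is None:
            raise ConfigError(f"covariate {name!r} has no parameters for stratum {stratum!r}")
        return params

    def residual_corr_matrix(self) -> np.ndarray:
        """3x3 residual correlation, order (ferritin, iron, TS)."""
        r_fi = self.residual_corr["ferritin_iron"]
        r_ft = self.residual_corr["ferritin_ts"]
        r_it = self.residual_corr["iron_ts"]
        return np.array([[1.0, r_fi, r_ft], [r_fi, 1.0, r_it], [r_ft, r_it, 1.0]])

    # --------------------------------------------------------- validation
    def validate(self) -> None:
        if self.n_pre < 0 or self.n_post < 0:
            raise ConfigError("stratum sizes must be non-negative")
        if self.n_menopause_missing < 0 or self.n_menopause_missing > self.n_total:
            raise ConfigError("n_menopause_missing out of range")
        if not 0 <= self.n_all_missing_outcomes <= self.n_total:
            raise ConfigError("n_all_missing_outcomes must lie in [0, n_pre + n_post]")

        for name, spec in self.covariates.items():
            family = spec.get("family")
            if family not in FAMILIES:
                raise ConfigError(f"covariate {name!r}: unknown family {family!r}")
            if family == "bernoulli":
                for stratum in STRATA:
                    params = spec.get(stratum)
                    if params is None:
                        continue
                    p = params.get("p")
                    if p is None or not 0.0 <= p <= 1.0:
                        raise ConfigError(
                            f"covariate {name!r}: prevalence for {stratum!r} must be in [0, 1]"
                        )
            if family in ("truncnorm", "lognormal"):
                for stratum in STRATA:
                    params = spec.get(stratum)
                    if params is None:
                        continue
                    scale = params.get("scale", params.get("sigma_log"))
                    if scale is None or scale < 0:
                        raise ConfigError(f"covariate {name!r}: negative scale for {stratum!r}")

        valid_names = set(self.covariates) | {schema.MENOPAUSE_COLUMN}
        for outcome, per_stratum in self.betas.items():
            if outcome not in OUTCOME_KEYS:
                raise ConfigError(f"unknown outcome key {outcome!r} in betas")
            for stratum, coef_map in per_stratum.items():
                for key in coef_map:
                    if key not in valid_names:
                        raise ConfigError(
                            f"coefficient key {key!r} ({outcome}/{stratum}) names no "
                            f"configured covariate"
                        )

        for outcome in OUTCOME_KEYS:
            for stratum in STRATA:
                sd = self.sigma.get(outcome, {}).get(stratum)
                if sd is None or sd <= 0:
                    raise ConfigError(f"residual SD for {outcome}/{stratum} must be > 0")

        for key in RESIDUAL_CORR_KEYS:
            rho = self.residual_corr.get(key)
            if rho is None or not -1.0 < rho < 1.0:
                raise ConfigError(f"residual correlation {key!r} must lie in (-1, 1)")
        if np.linalg.eigvalsh(self.residual_corr_matrix()).min() <= 0:
            raise ConfigError("residual correlation matrix is not positive definite")

        miss = self.missingness
        for var, per_stratum in miss.get("predictor_rates", {}).items():
            if var not in self.covariates:
                raise ConfigError(f"missingness rate for unknown variable {var!r}")
            for stratum, rate in per_stratum.items():
                if not 0.0 <= rate <= 1.0:
                    raise ConfigError(f"missing rate for {var!r}/{stratum} outside [0, 1]")
        for marker, rate in miss.get("outcome_rates", {}).items():
            if marker not in schema.SERUM_MARKERS:
                raise ConfigError(f"outcome missingness for unknown marker {marker!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"outcome missing rate for {marker!r} outside [0, 1]")
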