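"""Shared fixtures: scaled-down generator configurations and cohorts.

The small configuration keeps the default calibrated structure but shrinks
the strata and lifts the rarest binary conditions to 20% prevalence so that
no predictor column is constant at test sample sizes.
"""
from __future__ import annotations

import copy

import pytest
from hypothesis import HealthCheck, settings

from ironpred.config import GeneratorConfig
from ironpred.generate import generate_cohort, impose_missingness
from ironpred.mi import impute
from ironpred.preprocess import exclude_all_missing_outcomes

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

RARE_BINARIES = ("ibd_ever", "pcos_ever", "preeclampsia_ever", "ida_ever")


def boosted_covariates(cfg: GeneratorConfig, p: float = 0.2) -> dict:
    cov = copy.deepcopy(cfg.covariates)
    for var in RARE_BINARIES:
        for stratum in ("pre", "post"):
            cov[var][stratum]["p"] = p
    return cov


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig.default()


@pytest.fixture(scope="session")
def small_config(default_config) -> GeneratorConfig:
    return default_config.replace(
        covariates=boosted_covariates(default_config),
        n_pre=160,
        n_post=220,
        n_all_missing_outcomes=5,
        n_menopause_missing=1,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_observed(small_config, small_cohort):
    return impose_missingness(small_cohort, small_config)


@pytest.fixture(scope="session")
def small_stack(small_config, small_observed):
    analyzed = exclude_all_missing_outcomes(small_observed)
    return impute(analyzed, m=3, n_iter=3, seed=11)


@pytest.fixture(scope="session")
def medium_pre_config(default_config) -> GeneratorConfig:
    """A single premenopausal stratum large enough for sign/recovery checks."""
    return default_config.replace(
        covariates=boosted_covariates(default_config, p=0.15),
        n_pre=900,
        n_post=0,
        n_all_missing_outcomes=0,
        n_menopause_missing=0,
        seed=202,
    )


@pytest.fixture(scope="session")
def medium_pre_stack(medium_pre_config):
    observed = impose_missingness(generate_cohort(medium_pre_config), medium_pre_config)
    return impute(observed, m=3, n_iter=5, seed=21)


@pytest.fixture(scope="session")
def default_observed(default_config):
    """One full-size default cohort with missingness (shared: ~2 s to build)."""
    return impose_missingness(generate_cohort(default_config), default_config)
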