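"""Published reference surfaces used to parameterize the default generator.

Collects, in one place, the printed cohort summary statistics (stratum sizes,
covariate medians/IQRs, binary prevalences) and the stratum-specific
multivariable ML coefficient maps for the three ln-scale serum outcomes, plus
the calibration targets (outcome Spearman structure, apparent R², any-missing
fractions).  Residual SDs, residual correlations and the missing-rate scale
factors are free parameters with no published value; their shipped defaults
are produced by :func:`ironpred.generate.calibrate_generator` from these
targets (see ``analysis/00_calibrate_generator.py``).

Where the source tables give no marginal (alcohol in drinks/month, exercise in
hours/month, red meat in oz-eq/week, estrogen/progesterone years, history of
iron-deficiency anemia), a single field-realistic choice is documented in
``docs/methods.md``.
"""
from __future__ import annotations

import copy

from .config import GeneratorConfig

#: generated stratum sizes: after removing the planted 29 all-missing-outcome
#: rows and 2 menopause-missing rows, the analyzed strata are 2106 / 1063
#: (3171 retained, 3169 with observed menopause).
N_PRE_GENERATED = 1074
N_POST_GENERATED = 2126
N_ALL_MISSING = 29
N_MENOPAUSE_MISSING = 2

OUTCOME_MEDIANS = {
    "ferritin": {"pre": 40.0, "post": 80.0},
    "serum_iron": {"pre": 92.0, "post": 93.0},
    "transferrin_saturation": {"pre": 28.0, "post": 29.0},
}

#: scale = IQR width / 1.349 (normal-quantile spacing)
COVARIATES = {
    "age": {
        "family": "truncnorm",
        "pre": {"loc": 46.7, "scale": 5.41, "lower": 35.0, "upper": 62.0},
        "post": {"loc": 59.5, "scale": 7.12, "lower": 40.0, "upper": 74.0},
    },
    "bmi": {
        "family": "truncnorm",
        "pre": {"loc": 25.91, "scale": 5.80, "lower": 15.0, "upper": 60.0},
        "post": {"loc": 26.70, "scale": 5.85, "lower": 15.0, "upper": 60.0},
    },
    "alcohol": {  # drinks/month; no published marginal
        "family": "lognormal",
        "pre": {"median": 4.0, "sigma_log": 0.8, "upper": 60.0},
        "post": {"median": 3.0, "sigma_log": 0.8, "upper": 60.0},
    },
    "exercise": {  # hours/month; no published marginal
        "family": "lognormal",
        "pre": {"median": 6.0, "sigma_log": 0.7, "upper": 90.0},
        "post": {"median": 5.0, "sigma_log": 0.7, "upper": 90.0},
    },
    "meat": {  # red meat, oz-eq/week; no published marginal
        "family": "lognormal",
        "pre": {"median": 4.0, "sigma_log": 0.5, "upper": 30.0},
        "post": {"median": 4.0, "sigma_log": 0.5, "upper": 30.0},
    },
    "dietary_supp_iron": {  # mg/day
        "family": "lognormal",
        "pre": {"median": 18.7, "sigma_log": 0.70, "upper": 150.0},
        "post": {"median": 24.6, "sigma_log": 0.64, "upper": 150.0},
    },
    "dietary_supp_calcium": {  # mg/day (modeled in dg)
        "family": "lognormal",
        "pre": {"median": 947.7, "sigma_log": 0.67, "upper": 6000.0},
        "post": {"median": 1472.7, "sigma_log": 0.58, "upper": 6000.0},
    },
    "years_pregnant_breastfeeding": {
        "family": "lognormal",
        "pre": {"median": 2.94, "sigma_log": 0.9, "upper": 20.0},
        "post": {"median": 2.56, "sigma_log": 0.8, "upper": 20.0},
    },
    "aspirin": {"family": "bernoulli", "pre": {"p": 0.166}, "post": {"p": 0.358}},
    "statin": {"family": "bernoulli", "pre": {"p": 0.134}, "post": {"p": 0.311}},
    "blood_donation_12mo": {"family": "bernoulli", "pre": {"p": 0.164}, "post": {"p": 0.127}},
    "ida_ever": {"family": "bernoulli", "pre": {"p": 0.10}, "post": {"p": 0.08}},  # chosen
    "polyps_ever": {"family": "bernoulli", "pre": {"p": 0.079}, "post": {"p": 0.232}},
    "ibd_ever": {"family": "bernoulli", "pre": {"p": 0.010}, "post": {"p": 0.016}},
    "pcos_ever": {"family": "bernoulli", "pre": {"p": 0.029}, "post": {"p": 0.024}},
    "preeclampsia_ever": {"family": "bernoulli", "pre": {"p": 0.074}, "post": {"p": 0.052}},
    "ep_use_years": {  # estrogen/progesterone years; no published marginal
        "family": "lognormal",
        "post_only": True,
        "post": {"median": 1.5, "sigma_log": 1.0, "upper": 35.0},
    },
    "reproductive_lifespan": {"family": "derived", "post_only": True},
    "years_since_lmp": {"family": "derived", "post_only": True},
}

MENOPAUSE_LINK = {
    "age_menopause_mean": 50.5,
    "age_menopause_sd": 4.0,
    "age_menopause_lower": 30.0,
    "age_menopause_upper": 58.0,
    "min_years_since": 0.5,
    "menarche_mean": 13.0,
    "menarche_sd": 1.5,
    "menarche_lower": 9.0,
    "menarche_upper": 18.0,
}

#: full-model ML coefficients per ln outcome and stratum (calcium per dg)
BETAS = {
    "ferritin": {
        "pre": {
            "age": 0.014, "aspirin": 0.098, "statin": 0.140,
            "blood_donation_12mo": -0.700, "ida_ever": -0.347,
            "polyps_ever": 0.016, "ibd_ever": 0.592, "pcos_ever": 0.112,
            "preeclampsia_ever": 0.388, "alcohol": 0.008, "bmi": 0.008,
            "exercise": 0.003, "years_pregnant_breastfeeding": -0.009,
            "dietary_supp_calcium": -0.003, "dietary_supp_iron": 0.002,
            "meat": 0.016,
        },
        "post": {
            "age": 0.013, "aspirin": 0.056, "statin": 0.024,
            "blood_donation_12mo": -1.121, "ida_ever": -0.234,
            "polyps_ever": -0.046, "ibd_ever": 0.151, "pcos_ever": -0.056,
            "preeclampsia_ever": 0.107, "alcohol": 0.006, "bmi": 0.003,
            "exercise": 0.000, "ep_use_years": -0.005,
            "reproductive_lifespan": -0.003,
            "years_pregnant_breastfeeding": -0.001, "years_since_lmp": 0.001,
            "dietary_supp_calcium": -0.014, "dietary_supp_iron": 0.001,
            "meat": 0.018,
        },
    },
    "serum_iron": {
        "pre": {
            "age": -0.005, "aspirin": 0.018, "statin": -0.008,
            "blood_donation_12mo": -0.253, "ida_ever": -0.175,
            "polyps_ever": -0.069, "ibd_ever": 0.038, "pcos_ever": -0.207,
            "preeclampsia_ever": 0.018, "alcohol": 0.006, "bmi": -0.030,
            "exercise": 0.007, "years_pregnant_breastfeeding": 0.001,
            "dietary_supp_calcium": 0.007, "dietary_supp_iron": 0.000,
            "meat": 0.004,
        },
        "post": {
            "age": 0.003, "aspirin": 0.125, "statin": -0.081,
            "blood_donation_12mo": -0.167, "ida_ever": -0.101,
            "polyps_ever": -0.067, "ibd_ever": 0.260, "pcos_ever": -0.024,
            "preeclampsia_ever": -0.015, "alcohol": 0.004, "bmi": -0.033,
            "exercise": 0.004, "ep_use_years": 0.007,
            "reproductive_lifespan": 0.002,
            "years_pregnant_breastfeeding": 0.001, "years_since_lmp": -0.007,
            "dietary_supp_calcium": 0.003, "dietary_supp_iron": -0.002,
            "meat": 0.006,
        },
    },
    "transferrin_saturation": {
        "pre": {
            "age": -0.002, "aspirin": 0.019, "statin": -0.042,
            "blood_donation_12mo": -0.394, "ida_ever": -0.214,
            "polyps_ever": 0.010, "ibd_ever": 0.124, "pcos_ever": -0.181,
            "preeclampsia_ever": 0.089, "alcohol": 0.004, "bmi": -0.033,
            "exercise": 0.005, "years_pregnant_breastfeeding": -0.004,
            "dietary_supp_calcium": 0.004, "dietary_supp_iron": 0.001,
            "meat": 0.003,
        },
        "post": {
            "age": 0.010, "aspirin": 0.134, "statin": -0.119,
            "blood_donation_12mo": -0.406, "ida_ever": -0.105,
            "polyps_ever": -0.067, "ibd_ever": 0.240, "pcos_ever": -0.133,
            "preeclampsia_ever": -0.003, "alcohol": 0.002, "bmi": -0.037,
            "exercise": 0.003, "ep_use_years": 0.004,
            "reproductive_lifespan": 0.000,
            "years_pregnant_breastfeeding": -0.002, "years_since_lmp": -0.008,
            "dietary_supp_calcium": -0.004, "dietary_supp_iron": -0.001,
            "meat": 0.010,
        },
    },
}

#: placeholder residual structure; overwritten by calibration
SIGMA_START = {
    "ferritin": {"pre": 0.85, "post": 0.85},
    "serum_iron": {"pre": 0.60, "post": 0.60},
    "transferrin_saturation": {"pre": 0.60, "post": 0.60},
}
RESIDUAL_CORR_START = {"iron_ts": 0.92, "ferritin_iron": 0.20, "ferritin_ts": 0.33}

#: per-variable missing-rate profile (relative shape from the published
#: per-variable n's; stratum scale factors are calibrated)
MISSINGNESS = {
    "dependence": {"age": 0.35, "bmi": 0.35},
    "rate_caps": {"pre": 0.08, "post": 0.14},
    "predictor_rates": {
        "bmi": {"pre": 0.001, "post": 0.001},
        "alcohol": {"pre": 0.064, "post": 0.064},
        "exercise": {"pre": 0.010, "post": 0.010},
        "meat": {"pre": 0.023, "post": 0.023},
        "dietary_supp_iron": {"pre": 0.023, "post": 0.023},
        "dietary_supp_calcium": {"pre": 0.023, "post": 0.023},
        "years_pregnant_breastfeeding": {"pre": 0.006, "post": 0.006},
        "aspirin": {"pre": 0.021, "post": 0.021},
        "statin": {"pre": 0.020, "post": 0.020},
        "blood_donation_12mo": {"pre": 0.002, "post": 0.002},
        "ida_ever": {"pre": 0.020, "post": 0.020},
        "polyps_ever": {"pre": 0.080, "post": 0.113},
        "ibd_ever": {"pre": 0.013, "post": 0.013},
        "pcos_ever": {"pre": 0.037, "post": 0.037},
        "preeclampsia_ever": {"pre": 0.003, "post": 0.003},
        "ep_use_years": {"post": 0.020},
        "reproductive_lifespan": {"post": 0.002},
        "years_since_lmp": {"post": 0.001},
    },
    "outcome_rates": {"serum_iron": 0.007, "ferritin": 0.006, "uibc": 0.058},
}

DEFAULT_SEED = 20230901


def base_config(seed: int = DEFAULT_SEED) -> GeneratorConfig:
    """The pre-calibration configuration (published marginals + coefficients)."""
    return GeneratorConfig(
        seed=seed,
        n_pre=N_PRE_GENERATED,
        n_post=N_POST_GENERATED,
        n_menopause_missing=N_MENOPAUSE_MISSING,
        n_all_missing_outcomes=N_ALL_MISSING,
        covariates=copy.deepcopy(COVARIATES),
        menopause_link=dict(MENOPAUSE_LINK),
        outcome_medians=copy.deepcopy(OUTCOME_MEDIANS),
        betas=copy.deepcopy(BETAS),
        sigma=copy.deepcopy(SIGMA_START),
        residual_corr=dict(RESIDUAL_CORR_START),
        missingness=copy.deepcopy(MISSINGNESS),
    )


def calibration_targets() -> dict[str, float]:
    """Published summary statistics the calibration search aims for."""
    return {
        "apparent_r2:ferritin:pre": 0.134,
        "apparent_r2:ferritin:post": 0.189,
        "apparent_r2:ferritin:combined": 0.31,
        "apparent_r2:serum_iron:pre": 0.065,
        "apparent_r2:serum_iron:post": 0.064,
        "apparent_r2:transferrin_saturation:pre": 0.071,
        "apparent_r2:transferrin_saturation:post": 0.086,
        "spearman:serum_iron:transferrin_saturation": 0.92,
        "spearman:ferritin:serum_iron": 0.21,
        "spearman:ferritin:transferrin_saturation": 0.34,
        "any_missing:pre": 0.17,
        "any_missing:post": 0.24,
    }
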