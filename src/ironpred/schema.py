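"""Column vocabulary for the participant-level cohort table.

One row per participant.  Serum outcomes are stored on their natural scale
(iron and ferritin in mcg/dL, UIBC in the same units as iron, transferrin
saturation in percent); models operate on the natural-log scale.  Calcium is
stored in mg and enters models in decigrams (handled by a model-spec
transform, never by mutating the data).
"""
from __future__ import annotations

ID_COLUMN = "participant_id"
MENOPAUSE_COLUMN = "menopause"  # 1 = postmenopausal at baseline, 0 = premenopausal

OUTCOME_COLUMNS = ["serum_iron", "ferritin", "uibc", "transferrin_saturation"]
#: the three assayed serum markers; transferrin saturation is derived from
#: iron and UIBC and is missing whenever either of those is.
SERUM_MARKERS = ["serum_iron", "ferritin", "uibc"]

CONTINUOUS_PREDICTORS = [
    "age",                            # years
    "bmi",                            # kg/m^2
    "alcohol",                        # drinks/month
    "exercise",                       # hours/month
    "meat",                           # oz-eq/week (red meat)
    "dietary_supp_iron",              # mg/day, diet + supplements
    "dietary_supp_calcium",           # mg/day, diet + supplements (modeled in dg)
    "years_pregnant_breastfeeding",   # years
]

BINARY_PREDICTORS = [
    "aspirin",
    "statin",
    "blood_donation_12mo",
    "ida_ever",
    "polyps_ever",
    "ibd_ever",
    "pcos_ever",
    "preeclampsia_ever",
]

#: defined only for postmenopausal women; structurally missing otherwise.
POST_ONLY_PREDICTORS = [
    "ep_use_years",          # estrogen/progesterone use, total years
    "reproductive_lifespan", # age at last menstrual period - age at menarche
    "years_since_lmp",       # years since last menstrual period
]

COMMON_PREDICTORS = CONTINUOUS_PREDICTORS + BINARY_PREDICTORS

PREDICTORS_BY_STRATUM = {
    "pre": list(COMMON_PREDICTORS),
    "post": list(COMMON_PREDICTORS) + list(POST_ONLY_PREDICTORS),
    # the combined model can only use variables defined in both strata, plus
    # the menopause indicator itself
    "combined": list(COMMON_PREDICTORS) + [MENOPAUSE_COLUMN],
}

ALL_PREDICTORS = COMMON_PREDICTORS + POST_ONLY_PREDICTORS

ALL_COLUMNS = (
    [ID_COLUMN, MENOPAUSE_COLUMN]
    + OUTCOME_COLUMNS
    + CONTINUOUS_PREDICTORS
    + BINARY_PREDICTORS
    + POST_ONLY_PREDICTORS
)

#: outcome key (model vocabulary) -> raw cohort column
OUTCOME_COLUMN_BY_KEY = {
    "ferritin": "ferritin",
    "serum_iron": "serum_iron",
    "transferrin_saturation": "transferrin_saturation",
}

#: model outcome names (always fit on the ln scale)
MODEL_OUTCOMES = {
    "ln_ferritin": "ferritin",
    "ln_iron": "serum_iron",
    "ln_ts": "transferrin_saturation",
}
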