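"""Cohort table serialization: CSV with a JSON sidecar of column metadata.

Empty cells encode missing values (structural and MAR missingness collapse to
the same code on export, as in a real questionnaire extract).
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import schema

_SIDECAR_SUFFIX = ".meta.json"

_COLUMN_META = {
    "participant_id": {"type": "int", "unit": None},
    "menopause": {"type": "binary", "unit": "1 = postmenopausal at baseline"},
    "serum_iron": {"type": "float", "unit": "mcg/dL"},
    "ferritin": {"type": "float", "unit": "mcg/dL"},
    "uibc": {"type": "float", "unit": "mcg/dL"},
    "transferrin_saturation": {"type": "float", "unit": "percent"},
    "age": {"type": "float", "unit": "years"},
    "bmi": {"type": "float", "unit": "kg/m^2"},
    "alcohol": {"type": "float", "unit": "drinks/month"},
    "exercise": {"type": "float", "unit": "hours/month"},
    "meat": {"type": "float", "unit": "oz-eq/week"},
    "dietary_supp_iron": {"type": "float", "unit": "mg/day"},
    "dietary_supp_calcium": {"type": "float", "unit": "mg/day (modeled in dg)"},
    "years_pregnant_breastfeeding": {"type": "float", "unit": "years"},
    "ep_use_years": {"type": "float", "unit": "years", "post_only": True},
    "reproductive_lifespan": {"type": "float", "unit": "years", "post_only": True},
    "years_since_lmp": {"type": "float", "unit": "years", "post_only": True},
}
for _b in schema.BINARY_PREDICTORS:
    _COLUMN_META[_b] = {"type": "binary", "unit": None}


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as UTF-8 CSV (empty cell = missing) + JSON sidecar."""
    path = Path(path)
    cohort.to_csv(path, index=False, na_rep="")
    meta = {
        "n_rows": int(len(cohort)),
        "columns": {c: _COLUMN_META.get(c, {"type": "float", "unit": None})
                    for c in cohort.columns},
    }
    with open(path.with_suffix(path.suffix + _SIDECAR_SUFFIX), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` (sidecar optional)."""
    df = pd.read_csv(path)
    missing = [c for c in (schema.ID_COLUMN, schema.MENOPAUSE_COLUMN) if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks required columns: {missing}")
    return df
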