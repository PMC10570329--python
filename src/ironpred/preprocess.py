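"""Sample construction, outcome derivation, stratification and descriptives.

Reproduces the analysis-sample pipeline: drop participants missing all three
serum markers, derive transferrin saturation from iron and UIBC, stratify by
menopause status at baseline, and summarize each stratum as median [IQR] /
n (%) plus the pairwise Spearman structure of the three outcomes.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import schema

logger = logging.getLogger(__name__)


def exclude_all_missing_outcomes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop rows where iron, ferritin and UIBC are all missing.

    A row with any one marker present is retained.  Row order is preserved;
    the number of removed rows is logged and stored in ``attrs['n_excluded']``.
    Idempotent.
    """
    mask = cohort[schema.SERUM_MARKERS].isna().all(axis=1)
    kept = cohort.loc[~mask].copy()
    kept.attrs["n_excluded"] = int(mask.sum())
    logger.info("excluded %d rows missing all serum markers (%d retained)",
                int(mask.sum()), len(kept))
    return kept


def compute_transferrin_saturation(iron, uibc):
    """Transferrin saturation (%) = 100 * iron / (iron + uibc).

    Accepts scalars or array-likes; missing whenever either input is missing,
    and missing (with a warning) when iron + uibc == 0.  Negative inputs are
    rejected: serum iron must be positive and UIBC non-negative.
    """
    iron_arr = np.asarray(iron, dtype=float)
    uibc_arr = np.asarray(uibc, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(iron_arr[~np.isnan(iron_arr)] < 0) or np.any(uibc_arr[~np.isnan(uibc_arr)] < 0):
            raise ValueError("serum iron and UIBC must be non-negative")
    denom = iron_arr + uibc_arr
    zero = denom == 0
    if np.any(zero):
        warnings.warn("iron + UIBC == 0: transferrin saturation undefined, set missing")
    with np.errstate(invalid="ignore", divide="ignore"):
        ts = np.where(zero, np.nan, 100.0 * iron_arr / denom)
    if np.ndim(iron) == 0 and np.ndim(uibc) == 0:
        return float(ts) if not np.isnan(ts) else float("nan")
    return ts


def stratify_by_menopause(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into (postmenopausal, premenopausal) tables.

    Rows with missing menopause status are excluded from both strata; their
    count is logged and stored on each returned table's attrs.
    """
    meno = cohort[schema.MENOPAUSE_COLUMN]
    n_unknown = int(meno.isna().sum())
    post = cohort.loc[meno == 1.0].copy()
    pre = cohort.loc[meno == 0.0].copy()
    for part in (post, pre):
        part.attrs["n_menopause_missing"] = n_unknown
    if n_unknown:
        logger.info("%d rows with unknown menopause status excluded from strata", n_unknown)
    return post, pre


@dataclass
class DescriptiveSummary:
    """Stratum-style descriptives: median [IQR] / n (%) and outcome Spearman."""

    continuous: pd.DataFrame   # index: variable; columns: n, median, iqr_low, iqr_high
    categorical: pd.DataFrame  # index: variable; columns: n, count, percent
    spearman: pd.DataFrame     # pairwise-complete Spearman of the 3 outcomes
    flagged: list[str] = field(default_factory=list)  # all-missing columns

    def to_csv(self, path) -> None:
        blocks = []
        cont = self.continuous.copy()
        cont.insert(0, "type", "continuous")
        blocks.append(cont)
        cat = self.categorical.copy()
        cat.insert(0, "type", "categorical")
        blocks.append(cat)
        pd.concat(blocks).to_csv(path, index_label="variable")


_SPEARMAN_OUTCOMES = ["serum_iron", "ferritin", "transferrin_saturation"]


def describe(cohort: pd.DataFrame) -> DescriptiveSummary:
    """Median/IQR for continuous variables, n (%) for binaries, outcome Spearman.

    Quartiles use linear interpolation between order statistics; Spearman uses
    average ranks and pairwise-complete observations.  An all-missing column is
    flagged rather than raising.
    """
    continuous_vars = (
        schema.OUTCOME_COLUMNS + schema.CONTINUOUS_PREDICTORS + schema.POST_ONLY_PREDICTORS
    )
    binary_vars = schema.BINARY_PREDICTORS + [schema.MENOPAUSE_COLUMN]

    flagged: list[str] = []
    cont_rows = {}
    for var in continuous_vars:
        if var not in cohort.columns:
            continue
        x = cohort[var].dropna()
        if x.empty:
            flagged.append(var)
            cont_rows[var] = {"n": 0, "median": np.nan, "iqr_low": np.nan, "iqr_high": np.nan}
            continue
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
        cont_rows[var] = {"n": len(x), "median": med, "iqr_low": q1, "iqr_high": q3}

    cat_rows = {}
    for var in binary_vars:
        if var not in cohort.columns:
            continue
        x = cohort[var].dropna()
        if x.empty:
            flagged.append(var)
            cat_rows[var] = {"n": 0, "count": 0, "percent": np.nan}
            continue
        count = int((x == 1.0).sum())
        cat_rows[var] = {"n": len(x), "count": count, "percent": 100.0 * count / len(x)}

    present = [v for v in _SPEARMAN_OUTCOMES if v in cohort.columns]
    rho = pd.DataFrame(np.eye(len(present)), index=present, columns=present)
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            sub = cohort[[a, b]].dropna()
            if len(sub) >= 2:
                r = float(stats.spearmanr(sub[a], sub[b]).statistic)
            else:
                r = np.nan
            rho.loc[a, b] = rho.loc[b, a] = r

    return DescriptiveSummary(
        continuous=pd.DataFrame.from_dict(cont_rows, orient="index"),
        categorical=pd.DataFrame.from_dict(cat_rows, orient="index"),
        spearman=rho,
        flagged=flagged,
    )
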