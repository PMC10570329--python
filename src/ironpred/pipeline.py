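"""End-to-end orchestration: generate/load → exclude → stratify → describe →
impute → fit (univariable, full, backward, lasso) → validate, with
table-shaped CSV outputs, JSON reports and a hash-stamped run manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, preprocess, schema
from .config import GeneratorConfig
from .generate import generate_cohort, impose_missingness
from .mi import ImputedStack, impute
from .models import ModelSpec, backward_select, fit_full, stacked_lasso
from .validation import validate_mi

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Run-level knobs for the full pipeline."""

    generator: GeneratorConfig | None = None   # or provide input_csv
    input_csv: str | None = None
    m: int = 5
    n_iter: int = 10
    B: int = 200
    p_threshold: float = 0.05
    alpha: float = 1.0
    n_folds: int = 10
    strata: list[str] = field(default_factory=lambda: ["pre", "post", "combined"])
    outcomes: list[str] = field(default_factory=lambda: ["ln_ferritin", "ln_iron", "ln_ts"])
    seed: int = 0
    out_dir: str = "results/run"
    complete_case: bool = False   # skip MI, analyze complete rows only
    run_selection: bool = True
    run_validation: bool = True

    def validate(self) -> None:
        if self.m < 1 or self.B < 1:
            raise ValueError("m and B must be >= 1")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.generator is None and self.input_csv is None:
            raise ValueError("either a generator config or an input CSV is required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage error aborts with the stage name; partial outputs are kept.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"seed": config.seed, "stages": [], "counts": {}}

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - stage boundary
            _write_manifest(out, manifest)
            raise StageError(name, exc) from exc
        manifest["stages"].append(name)
        return result

    # ---- data
    if config.input_csv is not None:
        observed = stage("load", lambda: io.read_cohort(config.input_csv))
        manifest["counts"]["generated"] = len(observed)
    else:
        gen = config.generator
        complete = stage("generate", lambda: generate_cohort(gen))
        observed = stage("missingness", lambda: impose_missingness(complete, gen))
        manifest["counts"]["generated"] = len(observed)
    io.write_cohort(observed, out / "cohort.csv")

    analyzed = stage("exclude", lambda: preprocess.exclude_all_missing_outcomes(observed))
    manifest["counts"]["excluded_all_missing"] = analyzed.attrs.get("n_excluded", 0)
    manifest["counts"]["analyzed"] = len(analyzed)

    post, pre = stage("stratify", lambda: preprocess.stratify_by_menopause(analyzed))
    manifest["counts"]["post"] = len(post)
    manifest["counts"]["pre"] = len(pre)
    manifest["counts"]["menopause_missing"] = post.attrs.get("n_menopause_missing", 0)

    for name, frame in (("combined", analyzed), ("post", post), ("pre", pre)):
        summary = stage(f"describe:{name}", lambda f=frame: preprocess.describe(f))
        summary.to_csv(out / f"table1_{name}.csv")
        summary.spearman.to_csv(out / f"spearman_{name}.csv")

    # ---- imputation
    if config.complete_case:
        cc = analyzed.dropna(
            subset=[c for c in schema.COMMON_PREDICTORS if c in analyzed.columns]
        )
        stack = ImputedStack(m=1, datasets=[cc], seed=config.seed)
        manifest["counts"]["complete_case_rows"] = len(cc)
    else:
        stack = stage(
            "impute",
            lambda: impute(analyzed, m=config.m, n_iter=config.n_iter, seed=config.seed),
        )
    stack.save(out / "imputations")

    # ---- models + validation per outcome x stratum
    for outcome in config.outcomes:
        for stratum in config.strata:
            label = f"{outcome}_{stratum}"
            spec = ModelSpec(outcome, stratum)
            full = stage(f"fit:{label}", lambda s=spec: fit_full(stack, s))
            table = full.coefficient_table()
            table["r2_apparent"] = full.r2_apparent

            if config.run_selection:
                bw = stage(f"backward:{label}",
                           lambda s=spec: backward_select(stack, s, config.p_threshold))
                las = stage(f"lasso:{label}",
                            lambda s=spec: stacked_lasso(
                                stack, s, alpha=config.alpha,
                                n_folds=config.n_folds, seed=config.seed))
                table["backward"] = [
                    (bw.final_model.coefficients[i].qbar
                     if bw.final_model and i in bw.final_model.coefficients else np.nan)
                    for i in table.index
                ]
                table["lasso"] = [
                    (las.final_model.coefficients[i].qbar
                     if i in las.final_model.coefficients
                     and i in las.selected else np.nan)
                    for i in table.index
                ]
                with open(out / f"selection_{label}.json", "w", encoding="utf-8") as fh:
                    json.dump({"backward": bw.path, "lasso": las.path,
                               "backward_selected": bw.selected,
                               "lasso_selected": las.selected}, fh, indent=2)
            table.to_csv(out / f"model_{label}.csv", index_label="term")

            if config.run_validation:
                rep = stage(f"validate:{label}",
                            lambda s=spec: validate_mi(stack, s, B=config.B,
                                                       seed=config.seed))
                rep.to_json(out / f"validation_{label}.json")
                perf = pd.DataFrame(
                    {"value": [rep.r2_apparent, rep.slope_internal, rep.r2_corrected]},
                    index=["apparent_r2", "calibration_slope", "corrected_r2"],
                )
                perf.to_csv(out / f"performance_{label}.csv", index_label="statistic")

    manifest["runtime_s"] = round(time.time() - t0, 2)
    _write_manifest(out, manifest)
    logger.info("pipeline finished in %.1fs -> %s", manifest["runtime_s"], out)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    manifest["files"] = {
        p.name: _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)


def run_config_from_yaml(path) -> RunConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    gen = raw.pop("generator", None)
    cfg = RunConfig(**{k: v for k, v in raw.items()
                       if k in {f.name for f in dataclasses.fields(RunConfig)}})
    if isinstance(gen, str):
        cfg.generator = GeneratorConfig.from_yaml(gen)
    elif isinstance(gen, dict):
        cfg.generator = GeneratorConfig.from_dict(gen)
    elif gen is None and cfg.input_csv is None:
        cfg.generator = GeneratorConfig.default()
    return cfg
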