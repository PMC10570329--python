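"""Multivariable models and variable selection per outcome and stratum.

What it does: for each serum outcome and stratum fits the full ML model with
Rubin-pooled coefficients, runs pooled backward elimination (p < 0.05) and
the stacked lasso (CV-chosen penalty), and writes one coefficient table per
combination in the shape of the published model tables (ML estimate with 95%
CI next to the backward and lasso columns).
"""
import json
from pathlib import Path

from ironpred.mi import ImputedStack
from ironpred.models import ModelSpec, backward_select, fit_full, stacked_lasso

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 20230901) -> None:
    stack = ImputedStack.load(RESULTS / "imputations")
    for outcome in ("ln_ferritin", "ln_iron", "ln_ts"):
        for stratum in ("pre", "post", "combined"):
            spec = ModelSpec(outcome, stratum)
            full = fit_full(stack, spec)
            bw = backward_select(stack, spec)
            las = stacked_lasso(stack, spec, seed=seed)
            table = full.coefficient_table()
            table["backward"] = [
                bw.final_model.coefficients[t].qbar
                if bw.final_model and t in bw.final_model.coefficients else float("nan")
                for t in table.index
            ]
            table["lasso"] = [
                las.final_model.coefficients[t].qbar if t in las.selected else float("nan")
                for t in table.index
            ]
            label = f"{outcome}_{stratum}"
            table.to_csv(RESULTS / f"model_{label}.csv", index_label="term")
            with open(RESULTS / f"selection_{label}.json", "w", encoding="utf-8") as fh:
                json.dump({"backward_selected": bw.selected, "backward_path": bw.path,
                           "lasso_selected": las.selected, "lasso_path": las.path},
                          fh, indent=2)
            print(f"{label}: apparent R² {full.r2_apparent:.3f}; "
                  f"backward kept {len(bw.selected)}/{len(spec.predictors)}, "
                  f"lasso kept {len(las.selected)}")


if __name__ == "__main__":
    main()
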