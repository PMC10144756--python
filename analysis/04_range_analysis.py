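#!/usr/bin/env python
"""Range-partitioned accuracy: K, AL and AL/K strata plus LOESS trends.

Derives the K and AL cutoffs from the optimizable subset (quartiles rounded
to 1.00 D / 0.50 mm), partitions both analysis arms into the resulting
ranges (AL/K uses the fixed 0.67/0.75 cutoffs), computes the per-range
accuracy battery and paired tests, and writes LOESS trend curves of PE
against each stratifier.
"""

import json
from pathlib import Path

import pandas as pd

from postlrs import (
    ExternalPredictions,
    Method,
    alk_scheme,
    apply_constants,
    derive_cutoffs,
    loess_trend,
    optimize_all,
    per_range_comparison,
    read_cohort,
    read_external_predictions,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
METHODS = list(Method)


def range_table(results, arm, variable):
    rows = []
    for rc in results:
        for method, s in rc.summaries.items():
            rows.append({
                "arm": arm, "variable": variable, "range": rc.label,
                "n": rc.n, "method": method, "medae_d": s.medae,
                "pct_within_0_5": s.pct_within[0.5][1],
                "pct_within_1_0": s.pct_within[1.0][1],
                "best_in_range": method == rc.best_method,
                "friedman_p": rc.friedman.p if rc.friedman else None,
            })
    return pd.DataFrame(rows)


def main() -> None:
    records, _ = read_cohort(RESULTS / "cohort.csv")
    external = ExternalPredictions(
        read_external_predictions(RESULTS / "barrett_predictions.csv"))
    constants, groups, exclusions = optimize_all(records, METHODS, external)
    eligible = [r for r in records if r.eye_id not in exclusions]

    # cutoffs from the optimizable subset, reused for both arms
    k_scheme = derive_cutoffs([r.k for r in eligible], 1.0, variable="K")
    al_scheme = derive_cutoffs([r.al for r in eligible], 0.5, variable="AL")
    schemes = {"K": k_scheme, "AL": al_scheme, "ALK": alk_scheme()}
    print(f"cutoffs from the optimizable subset ({len(eligible)} eyes): "
          f"K {k_scheme.cutoffs} D, AL {al_scheme.cutoffs} mm, AL/K (0.67, 0.75)")

    arms = {
        "manufacturer": (records,
                         apply_constants(records, METHODS, None, external,
                                         barrett_constant=119.0)),
        "optimized": (eligible,
                      apply_constants(eligible, METHODS, constants, external)),
    }

    tables, winners, trend_rows = [], {}, []
    for arm, (recs, frame) in arms.items():
        pe_wide = frame.pivot(index="eye_id", columns="method", values="pe_d")
        values = {"K": pd.Series({r.eye_id: r.k for r in recs}),
                  "AL": pd.Series({r.eye_id: r.al for r in recs}),
                  "ALK": pd.Series({r.eye_id: r.al / r.k for r in recs})}
        for var, scheme in schemes.items():
            res = per_range_comparison(pe_wide, values[var], scheme)
            tables.append(range_table(res, arm, var))
            winners[f"{arm}:{var}"] = {rc.label: rc.best_method for rc in res}
            for method in pe_wide.columns:
                curve = loess_trend(values[var].loc[pe_wide.index].to_numpy(),
                                    pe_wide[method].to_numpy(), variable=var)
                trend_rows.append(pd.DataFrame({
                    "arm": arm, "variable": var, "method": method,
                    "x": curve.x, "fitted_pe_d": curve.fitted}))

    pd.concat(tables, ignore_index=True).to_csv(
        RESULTS / "range_accuracy.csv", index=False)
    pd.concat(trend_rows, ignore_index=True).to_csv(
        RESULTS / "loess_trends.csv", index=False)
    (RESULTS / "range_winners.json").write_text(
        json.dumps(winners, indent=2) + "\n")

    print("lowest-MedAE method per range:")
    for key, rows in winners.items():
        print(f"  {key}")
        for label, best in rows.items():
            print(f"    {label}: {best}")


if __name__ == "__main__":
    main()
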