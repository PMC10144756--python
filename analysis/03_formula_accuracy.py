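#!/usr/bin/env python
"""Whole-cohort accuracy comparison of the seven methods, both arms.

Arm 1 (manufacturer constants, all eyes) and arm 2 (constants optimized by
zeroing the mean error, optimizable eyes only): per-method accuracy battery
(ME, MedAE, MAE, CI, % within +-0.50/+-1.00 D), normality screen of the PEs,
one-sample t of the mean error against zero, Friedman with Bonferroni on the
absolute errors and Cochran Q on the threshold indicators.
"""

import json
from pathlib import Path

import pandas as pd

from postlrs import (
    ExternalPredictions,
    Method,
    apply_constants,
    cochran_q,
    friedman_with_bonferroni,
    ks_normality,
    one_sample_t,
    optimize_all,
    read_cohort,
    read_external_predictions,
    summarize,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
METHODS = list(Method)


def battery(frame: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for method, grp in frame.groupby("method", sort=False):
        s = summarize(grp["pe_d"].to_numpy())
        rows.append({
            "method": method, "n": s.n, "me_d": s.me, "medae_d": s.medae,
            "mae_d": s.mae, "se_d": s.se_mae, "min_d": s.min_abs,
            "max_d": s.max_abs, "iqr_d": s.iqr_abs,
            "ci_lo_d": s.ci95[0], "ci_hi_d": s.ci95[1],
            "pct_within_0_5": s.pct_within[0.5][1],
            "pct_within_1_0": s.pct_within[1.0][1],
        })
    return pd.DataFrame(rows)


def tests_block(pe_wide: pd.DataFrame) -> dict:
    out = {"per_method": {}}
    for m in pe_wide.columns:
        pes = pe_wide[m].to_numpy()
        t, p_t = one_sample_t(pes)
        out["per_method"][m] = {
            "ks_normality_p": ks_normality(pes),
            "t_me_vs_zero": t, "t_p": p_t,
        }
    fr = friedman_with_bonferroni(pe_wide.abs().to_numpy(), list(pe_wide.columns))
    out["friedman_abs_error"] = {
        "chi2": fr.statistic, "df": fr.df, "p": fr.p,
        "pairwise_bonferroni": {f"{a}|{b}": p for (a, b), p in fr.pairwise.items()},
    }
    for t in (0.5, 1.0):
        binary = (pe_wide.abs() <= t).astype(int).to_numpy()
        try:
            cq = cochran_q(binary, list(pe_wide.columns))
            out[f"cochran_q_within_{t}"] = {
                "q": cq.statistic, "df": cq.df, "p": cq.p,
                "pairwise_bonferroni": {f"{a}|{b}": p
                                        for (a, b), p in cq.pairwise.items()},
            }
        except ValueError:
            out[f"cochran_q_within_{t}"] = "undefined (all eyes concordant)"
    return out


def main() -> None:
    records, _ = read_cohort(RESULTS / "cohort.csv")
    external = ExternalPredictions(
        read_external_predictions(RESULTS / "barrett_predictions.csv"))

    arms = {}
    manu = apply_constants(records, METHODS, None, external,
                           barrett_constant=119.0)
    arms["manufacturer"] = manu

    constants, groups, exclusions = optimize_all(records, METHODS, external)
    eligible = [r for r in records if r.eye_id not in exclusions]
    arms["optimized"] = apply_constants(eligible, METHODS, constants, external)

    for arm, frame in arms.items():
        tab = battery(frame)
        tab.to_csv(RESULTS / f"accuracy_{arm}.csv", index=False)
        pe_wide = frame.pivot(index="eye_id", columns="method", values="pe_d")
        blocks = tests_block(pe_wide)
        (RESULTS / f"tests_{arm}.json").write_text(
            json.dumps(blocks, indent=2, default=float) + "\n")
        best = tab.loc[tab["medae_d"].idxmin()]
        print(f"[{arm}] n = {int(tab['n'].iloc[0])} eyes; "
              f"best MedAE: {best['method']} ({best['medae_d']:.2f} D); "
              f"Friedman p = {blocks['friedman_abs_error']['p']:.2e}")
        print(tab[["method", "me_d", "medae_d", "mae_d",
                   "pct_within_0_5", "pct_within_1_0"]]
              .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
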