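#!/usr/bin/env python
"""Cohort statistics: gated two-group tests, correlations, constrained fits.

Runs the full statistical layer on the simulated cohort from step 01:
per-variable normality-gated comparisons, the viscosity-vs-concentration
constrained quadratic per group, Spearman correlations, and TSG6
2^-ddCT fold changes. Writes results/cohort_report.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from hyalkit import simulate as sim, stats


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.sim / "cohort.csv")
    variables = [v for v in sim.DEFAULT_COHORT_EFFECTS] + ["viscosity_cp"]
    # floor undetectable cytokine readings before testing
    for var in ("tnfa_ngml", "ccl5_ngml"):
        df[var] = stats.floor_undetectable(df[var], floor=1.0 if var == "tnfa_ngml" else 0.01)
    report = stats.run_cohort_analysis(
        df,
        variables=variables,
        spearman_pairs=[("ha_sandwich_mgml", "ha_competitive_mgml"),
                        ("ha_sandwich_mgml", "viscosity_cp"),
                        ("hcha_au", "tnfa_ngml")],
        quad_fit=("ha_sandwich_mgml", "viscosity_cp"),
    )
    # TSG6 relative expression, healthy median anchored to fold 1.0
    fc = stats.ddct_fold_change(df["ct_tsg6"], df["ct_18s"], df["group"])
    report["tsg6_fold_change"] = {
        "healthy_median": float(np.median(fc[df.group == "healthy"])),
        "oa_median": float(np.median(fc[df.group == "OA"])),
    }
    (args.out / "cohort_report.json").write_text(json.dumps(report, indent=2, default=str))

    for var in ("mw_gel_kda", "tnfa_ngml", "hcha_au", "ccl11_ngml"):
        v = report["variables"][var]
        print(f"{var:16s} {v['branch']:8s} p={v['p_value']:.2g} effect={v['effect']:+.3g}")
    print("OA quadratic B2:", round(report["quad_fit"]["OA"]["B2"], 1),
          "(generator 434); healthy:", round(report["quad_fit"]["healthy"]["B2"], 1))
    print("TSG6 fold change medians:", report["tsg6_fold_change"])


if __name__ == "__main__":
    main()
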