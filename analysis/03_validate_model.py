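#!/usr/bin/env python
"""Validate the published model on the synthetic cohorts.

For the training-style cohort the risk categories are re-derived at the
15/50/85 centiles of the prognostic index (as in model development); for the
validation-style cohort the frozen published cutoffs are applied.  For each
cohort the script reports the calibration risk table (observed Kaplan-Meier
versus model-predicted mean survival: medians, 12-month survival, hazard
ratios against category 1) and discrimination (Harrell's c-index and
Royston-Sauerbrei R2_D with 200-replicate bootstrap CIs).

Writes risk_table_*.csv, calibration_curves_*.csv and discrimination_*.json
under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from prosash import load_published_model, metrics
from prosash.calibration import build_risk_table, predicted_mean_survival
from prosash.model_core import linear_predictor_batch, risk_category

RESULTS = Path(__file__).resolve().parents[1] / "results"


def validate(name: str, mode: str, reps: int, seed: int) -> None:
    model = load_published_model()
    df = pd.read_csv(RESULTS / f"cohort_{name}.csv")
    rt = build_risk_table(df, model, mode=mode)
    rt.to_csv(RESULTS / f"risk_table_{name}.csv")
    print(f"\n== {name} cohort (n={len(df)}, {mode} cutoffs) ==")
    cols = ["n", "observed_median", "predicted_median",
            "observed_pct_12m", "predicted_pct_12m", "hr"]
    print(rt.table[cols].round(2).to_string())

    etas = linear_predictor_batch(df, model)
    rows = []
    from prosash.model_core import RiskCutoffs
    cats = np.array([risk_category(e, RiskCutoffs(rt.cutoffs)) for e in etas])
    for c, km in rt.curves.items():
        pred = predicted_mean_survival(etas[cats == c], model, km.times)
        for t, s, lo, hi, ps in zip(km.times, km.survival, km.ci_lower,
                                    km.ci_upper, pred.survival):
            rows.append({"category": c, "t": t, "observed_S": s, "lower": lo,
                         "upper": hi, "predicted_S": ps})
    pd.DataFrame(rows).to_csv(RESULTS / f"calibration_curves_{name}.csv",
                              index=False, float_format="%.4f")

    disc = metrics.discrimination(df["time"], df["event"], etas,
                                  reps=reps, seed=seed)
    print(f"c-index {disc.c_index:.2f} "
          f"({disc.c_index_ci[0]:.2f}, {disc.c_index_ci[1]:.2f}); "
          f"R2_D {disc.r2_d:.2f} "
          f"({disc.r2_d_ci[0]:.2f}, {disc.r2_d_ci[1]:.2f})")
    (RESULTS / f"discrimination_{name}.json").write_text(
        json.dumps(disc.to_dict(), indent=2))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=200,
                    help="bootstrap replicates for the CIs")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    validate("training", "centile", args.reps, args.seed)
    validate("validation", "published", args.reps, args.seed + 1)


if __name__ == "__main__":
    main()
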