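#!/usr/bin/env python
"""Generate the synthetic training- and validation-style cohorts.

The real trial arms are proprietary, so the downstream analyses run on
synthetic cohorts drawn from the published model itself: a training-style
cohort of n=500 (the size of the complete-case training set) and a
validation-style cohort of n=450.  Covariates follow the published marginal
distributions; censoring mixes the ~31-month administrative horizon with
exponential dropout, landing the death fraction in the reported 70-80% band.

Writes results/cohort_training.csv and results/cohort_validation.csv with
provenance sidecars.
"""

import argparse
import json
import warnings
from pathlib import Path

from prosash import load_published_model
from prosash.synthetic_cohort import CohortConfig, generate_dataset

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    model = load_published_model()
    RESULTS.mkdir(exist_ok=True)
    for name, n, seed in (("training", 500, args.seed),
                          ("validation", 450, args.seed + 10_000)):
        cfg = CohortConfig(n=n, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = generate_dataset(cfg, model)
        out = RESULTS / f"cohort_{name}.csv"
        df.to_csv(out, index=False)
        (RESULTS / f"cohort_{name}.meta.json").write_text(json.dumps(
            {k: df.attrs[k] for k in
             ("seed", "config_hash", "model_version", "event_fraction")},
            indent=2))
        print(f"{name}: n={n}, seed={seed}, "
              f"event fraction {df.attrs['event_fraction']:.3f} -> {out}")


if __name__ == "__main__":
    main()
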