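#!/usr/bin/env python
"""Operating characteristics of the stability-selection procedure.

Replicates the whole study over fresh synthetic cohorts and measures how
the first-drop stable set behaves against the known ground truth: how often
planted effects that enter the stable set carry the correct sign, how often
any individual null connection intrudes, and the distribution of stable-set
sizes.  Writes results/recovery_rates.csv.
"""

import argparse
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from stutterconn.bootstrap import BootstrapConfig, build_selection_report, run_bootstrap
from stutterconn.lasso import LassoConfig
from stutterconn.synthetic import SimulationConfig, simulate_dataset

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--replicates", type=int, default=20)
    ap.add_argument("--n-boot", type=int, default=200)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    sign_ok = 0
    planted_seen = 0
    sizes = []
    null_hits: Counter = Counter()
    for r in range(args.replicates):
        s = args.seed * 1000 + r
        ds = simulate_dataset(SimulationConfig(seed=s))
        boot = BootstrapConfig(n_boot=args.n_boot, seed=s)
        res = run_bootstrap(ds.design, LassoConfig(), boot)
        rep = build_selection_report(res, boot)
        stable = set(rep.stable_set)
        sizes.append(len(stable))
        support = {ds.design.column_labels[k]: ds.truth[k] for k in ds.support}
        mean_by = dict(zip(rep.labels, rep.mean_coef))
        planted_in = stable & set(support)
        planted_seen += bool(planted_in)
        if all(np.sign(mean_by[l]) == np.sign(support[l]) for l in planted_in):
            sign_ok += 1
        for lbl in stable - set(support):
            null_hits[lbl] += 1

    R = args.replicates
    rows = [
        {"metric": "sign_consistency_rate", "value": sign_ok / R},
        {"metric": "replicates_with_planted_in_stable_set", "value": planted_seen / R},
        {"metric": "worst_null_intrusion_rate",
         "value": (max(null_hits.values()) if null_hits else 0) / R},
        {"metric": "median_stable_set_size", "value": float(np.median(sizes))},
    ]
    df = pd.DataFrame(rows)
    ROOT.mkdir(exist_ok=True)
    df.to_csv(ROOT / "recovery_rates.csv", index=False)
    print(df.to_string(index=False))
    print(f"({R} replicate cohorts, B={args.n_boot}; the planted signal is "
          "deliberately weak, so exact support recovery is rare while sign "
          "errors and recurrent null intrusions stay controlled)")


if __name__ == "__main__":
    main()
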