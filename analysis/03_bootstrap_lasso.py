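#!/usr/bin/env python
"""Bootstrapped cross-validated LASSO on the simulated cohort, all outcomes.

The headline analysis: for each disfluency type, 1000 paired bootstrap
resamples, a cross-validated penalty per resample, Bonferroni-adjusted
bootstrap-SE confidence intervals, stability selection and the first-drop
stable set.  Writes per-outcome report CSVs, run JSONs, figures and a
manifest under results/bootstrap_run/.  Run 02_simulate_cohort.py first.
"""

import argparse
from pathlib import Path

from stutterconn.bootstrap import BootstrapConfig
from stutterconn.lasso import LassoConfig
from stutterconn.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-boot", type=int, default=1000)
    args = ap.parse_args()

    sim = ROOT / "synthetic_cohort"
    cfg = RunConfig(
        behavioral_csv=str(sim / "behavioral.csv"),
        connectivity_csv=str(sim / "connectivity.csv"),
        lasso=LassoConfig(seed=args.seed),
        bootstrap=BootstrapConfig(n_boot=args.n_boot, seed=args.seed),
        out_dir=str(ROOT / "bootstrap_run"),
    )
    manifest = run_pipeline(cfg)
    for outcome, stable in manifest["stable_sets"].items():
        lam = manifest["avg_lambda"][outcome]
        print(f"{outcome:<13} avg optimal lambda {lam:.3f}  stable set: "
              f"{', '.join(stable) if stable else '(empty)'}")
    print(f"wrote {len(manifest['artifacts'])} artifacts to {ROOT / 'bootstrap_run'}")


if __name__ == "__main__":
    main()
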