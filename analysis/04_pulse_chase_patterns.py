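#!/usr/bin/env python
"""Pulse-chase incorporation patterns and the inward peak shift.

Generates pulse-chase populations (150 sarcomeres in 6 pseudo-myotubes)
at 7, 15 and 30 min of chase with the tip-biased population preset,
classifies every sarcomere into the eight red-peak patterns, and reports
category frequencies (mean ± SE across myotubes), the classifier's
agreement with ground truth, and the median red-peak-to-center distance
per chase time (which decreases as newly made myosin spreads inward).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from myoturnover.pipeline import PipelineConfig, run_pulse_chase_stage


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    parser.add_argument("--n-sarcomeres", type=int, default=150)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    config = PipelineConfig(
        seed=args.seed,
        out_dir=str(args.out_dir),
        pulse_chase_times_min=(7.0, 15.0, 30.0),
        pulse_chase_n_sarcomeres=args.n_sarcomeres,
        pulse_chase_n_myotubes=6,
    )
    classified, summary, outputs = run_pulse_chase_stage(
        config, args.out_dir, np.random.SeedSequence(args.seed)
    )

    truth = pd.read_csv(args.out_dir / "classification_truth.csv")
    agree = (truth["truth_category"] == truth["assigned_category"]).mean()
    print(f"classified {len(classified)} sarcomeres; ground-truth agreement {100 * agree:.1f}%")
    print("Category-group proportions (mean over myotubes):")
    for t, sub in summary.rollup.groupby("time_min"):
        parts = ", ".join(
            f"{r.group} {100 * r.mean:4.1f}% ± {100 * r.se:.1f}%" for r in sub.itertuples()
        )
        print(f"  {t:4.0f} min: {parts}")
    print("Median red-peak distance from the filament center:")
    for r in summary.medians.itertuples():
        print(f"  {r.time_min:4.0f} min: {r.median_distance:.2f} (n = {r.n_records} peaks)")
    print("wrote:", ", ".join(outputs))


if __name__ == "__main__":
    main()
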