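#!/usr/bin/env python
"""FRAP recovery experiment: mobile fraction and half-life per channel.

Simulates seven photoconversion ROI traces per channel with the
paper-calibrated monoexponential presets (green: insertion; red: release),
applies the bleaching / drift corrections and the exponential fit, and
compares the two channels with Student's t-test.  Writes frap_fits.csv,
frap_groups.csv and a recovery-curve figure under the output directory.
"""

import argparse
from pathlib import Path

import numpy as np

from myoturnover.pipeline import PipelineConfig, run_frap_stage


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    config = PipelineConfig(seed=args.seed, out_dir=str(args.out_dir))
    fits, groups, outputs = run_frap_stage(
        config, args.out_dir, np.random.SeedSequence(args.seed)
    )

    print("Per-channel recovery (mean over traces):")
    for channel, sub in fits.groupby("channel"):
        print(
            f"  {channel:5s}: Mf = {100 * sub['mf'].mean():5.2f}% "
            f"± {100 * sub['mf'].sem():.2f}% (SE), "
            f"t_1/2 = {sub['t_half_h'].mean():.2f} ± {sub['t_half_h'].sem():.2f} h "
            f"(n = {len(sub)})"
        )
    if not groups.empty:
        for row in groups.itertuples():
            print(
                f"  green vs red {row.quantity}: t = {row.t_statistic:+.2f}, "
                f"p = {row.p_value:.3f}"
            )
    print("wrote:", ", ".join(outputs))


if __name__ == "__main__":
    main()
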