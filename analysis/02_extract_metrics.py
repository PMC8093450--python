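#!/usr/bin/env python
"""Extract the per-recording workload metrics into results/metrics.csv.

One row per participant x condition x metric: pupil (L1NS/STDP/LPF per eye),
gaze (NNI, fixation rate, saccade rate, median SI velocity), EEG band powers
(theta/alpha/low-beta/high-beta medians), and inceptor/flight metrics (duty
cycle, aggressiveness, %RMSE altitude and airspeed). Prints the per-condition
means of a few headline metrics.

Usage: python analysis/02_extract_metrics.py [--study DIR]
"""

import argparse
import warnings
from pathlib import Path

from cogload import pipeline

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "scratch" / "study")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "metrics.csv")
    args = ap.parse_args()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pipeline.extract_metrics(args.study)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(f"{len(table)} metric rows -> {args.out}")

    wide = table.pivot_table(index="metric", columns="condition", values="value")
    headline = ["l1ns_right", "nni", "power_lb", "power_theta", "duty_cycle",
                "median_si_velocity", "fixation_rate"]
    print("\ncondition means:")
    print(wide.loc[headline].round(3).to_string())


if __name__ == "__main__":
    main()
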