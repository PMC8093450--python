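#!/usr/bin/env python
"""Simulate the flight-simulator study: 12 participants x 3 conditions.

C1 is the baseline flight task, C2 adds an altitude-band constraint, C3 adds
a secondary touchscreen task; their latent workload levels (0.25 / 0.45 /
0.90) drive the pupil 1-5 Hz component, fixation dispersion, EEG band
amplitudes, inceptor activity, and tracking error through the default effect
map. Writes the recordings under scratch/study/ (CSV per modality per cell)
plus a ground-truth manifest, and prints what was generated.

Usage: python analysis/01_simulate_study.py [--seed N] [--duration S]
"""

import argparse
import warnings
from pathlib import Path

from cogload import synthetic

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--duration", type=float, default=240.0,
                    help="recording length per cell, seconds")
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "study")
    args = ap.parse_args()

    cfg = synthetic.StudyConfig(duration_s=args.duration, seed=args.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = synthetic.gen_study(cfg, args.out, force=True)

    n = len(manifest["recordings"])
    print(f"wrote {n} recording sets ({cfg.participants} participants x "
          f"{len(cfg.conditions)} conditions) to {args.out}")
    for cond in cfg.conditions:
        print(f"  {cond.name}: workload {cond.workload}")


if __name__ == "__main__":
    main()
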