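#!/usr/bin/env python
"""Conformance analysis: Spearman rank correlations between modalities.

Pools all participant x condition recordings (36 points) and correlates the
EEG, ocular, and inceptor workload indices pairwise: low-beta vs theta power,
low-beta vs high-beta, NNI vs L1NS, L1NS vs low-beta, duty cycle vs L1NS, and
duty cycle vs theta. Positive correlations indicate the metrics move together
under the shared latent workload. Writes results/conformance.csv.

Usage: python analysis/04_conformance.py [--metrics results/metrics.csv]
"""

import argparse
from pathlib import Path

import pandas as pd

from cogload import pipeline

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--metrics", type=Path, default=ROOT / "results" / "metrics.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "conformance.csv")
    args = ap.parse_args()

    table = pd.read_csv(args.metrics)
    conf = pipeline.conformance(table)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    conf.to_csv(args.out, index=False)
    print(f"conformance matrix -> {args.out}\n")
    print(conf.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
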