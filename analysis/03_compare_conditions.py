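#!/usr/bin/env python
"""Condition comparison: outer fencing, normality gate, omnibus + pairwise tests.

For each metric the participants x conditions table is outer-fenced within
conditions, routed through the Anderson-Darling gate, then tested with
Friedman + pairwise Wilcoxon signed-rank (non-normal) or RM-ANOVA + paired t
(normal). Writes the full report JSON and the pairwise comparison matrix
(metric x condition pair, flagged at the 0.1/0.05/0.01 levels) as CSV, and
prints which metrics separate the condition with the secondary task.

Usage: python analysis/03_compare_conditions.py [--metrics results/metrics.csv]
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from cogload import pipeline

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--metrics", type=Path, default=ROOT / "results" / "metrics.csv")
    ap.add_argument("--out-json", type=Path, default=ROOT / "results" / "report.json")
    ap.add_argument("--out-csv", type=Path, default=ROOT / "results" / "comparison.csv")
    args = ap.parse_args()

    table = pd.read_csv(args.metrics)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = pipeline.analyze_study(table)
    args.out_json.parent.mkdir(parents=True, exist_ok=True)
    report.to_json(args.out_json)
    report.pairwise.to_csv(args.out_csv, index=False)
    print(f"report -> {args.out_json}\ncomparison matrix -> {args.out_csv}\n")

    matrix = report.pairwise.pivot_table(
        index="metric", columns="pair", values="flag", aggfunc="first"
    ).fillna("")
    print(matrix.to_string())
    c23 = report.pairwise[report.pairwise.pair == "C2-C3"]
    sig = sorted(c23[c23.flag != ""]["metric"])
    print(f"\nmetrics separating C2 vs C3 (secondary task): {', '.join(sig)}")


if __name__ == "__main__":
    main()
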