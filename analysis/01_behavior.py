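#!/usr/bin/env python
"""Simulate the reversal-learning behavior of all subjects and score it.

Generates six blocks (three per condition) for each of 22 simulated
subjects, scores accuracy, extinction and association errors, and runs the
2 x 3 repeated-measures ANOVA on reaction times with Bonferroni post hocs.
Tables are written to results/behavior_*.tsv.

Finding (seed 1): agents following the task rule with a small lapse (1%)
and perseveration (7%) rate land near-perfect accuracy with extinction
errors an order of magnitude above association errors, the signature of a
deterministic reversal task.
"""

import argparse
from pathlib import Path

from orfi_eeg import pipeline

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--subjects", type=int, default=22)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = pipeline.RunConfig(seed=args.seed, n_subjects=args.subjects)
    res = pipeline.behavior_stage(cfg, args.out)
    by_cond = res["behavior"].groupby("condition").mean(numeric_only=True)
    print(by_cond.round(2))
    print("\nRT omnibus:")
    for eff, row in res["rt_anova"]["omnibus"].items():
        print(f"  {eff}: F={row['F']:.2f} p={row['p']:.4f} eta2={row['partial_eta_sq']:.3f}")
    print(f"\ntables -> {args.out}/behavior_subjects.tsv, behavior_rt_posthoc.tsv")
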