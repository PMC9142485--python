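#!/usr/bin/env python
"""Run the entire pipeline (behavior -> EEG -> ERP -> TF -> source) once.

Thin wrapper over orfi_eeg.pipeline.run_all; stage outputs and a Markdown
report land in the output directory.  Stages whose configuration has not
changed are skipped on re-runs.
"""

import argparse
from pathlib import Path

from orfi_eeg import pipeline

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--subjects", type=int, default=22)
    ap.add_argument("--perms", type=int, default=5000)
    ap.add_argument("--out", type=Path, default=Path("results/full_run"))
    args = ap.parse_args()

    cfg = pipeline.RunConfig(
        seed=args.seed, n_subjects=args.subjects, n_perm_cluster=args.perms
    )
    pipeline.run_all(cfg, args.out)
    print(f"report -> {args.out}/report.md")
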