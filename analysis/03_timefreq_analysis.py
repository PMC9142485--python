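#!/usr/bin/env python
"""Time-frequency power analysis of the SIMI outcomes in both conditions.

Computes Hanning STFT power (3-45 Hz, 1 Hz step, 300 ms windows every
10 ms) on the frontal/central/posterior electrode clusters, converts to dB
against the -550..0 ms baseline, and compares SIMI(identical) with
SIMI(semantical) using the 2-D (frequency x time) cluster-permutation test.

Finding (seed 1, n=22): a significant low-frequency (3-9 Hz) power increase
for SIMI(identical) over the frontal and central clusters from ~110-140 ms
on (p = 0.002, cluster corrected) — the injected frontocentral theta effect
is recovered through the full chain.  The injected beta suppression is
weaker and does not reliably survive cluster correction at this sample size.
"""

import argparse
from pathlib import Path

from orfi_eeg import pipeline

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--subjects", type=int, default=22)
    ap.add_argument("--perms", type=int, default=5000)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = pipeline.RunConfig(
        seed=args.seed, n_subjects=args.subjects, n_perm_cluster=args.perms
    )
    eeg = pipeline.eeg_stage(cfg, args.out)
    tf = pipeline.timefreq_stage(cfg, args.out, eeg)
    if not tf["table"]:
        print("no significant time-frequency clusters")
    for row in tf["table"]:
        print(
            f"{row['cluster_set']}: {row['fmin_hz']:.0f}-{row['fmax_hz']:.0f} Hz, "
            f"{row['start_ms']:.0f}-{row['end_ms']:.0f} ms, sign {row['sign']:+d}, "
            f"p={row['p_corrected']:.4f}"
        )
    print(f"table -> {args.out}/tf_cluster_simi_contrast.tsv")
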