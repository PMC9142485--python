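#!/usr/bin/env python
"""Beamformer source analysis of the SIMI theta contrast.

Builds the 10-mm lead field on the spherical head model, projects each
subject's SIMI epochs through the scalar minimum-variance beamformer
(300 ms Hanning windows stepped 50 ms, five frequency bands), converts per
voxel to dB against the -550..0 ms baseline, and contrasts the conditions
at the theta band / +300 ms window with SnPM-style sign-flip permutation
statistics and spatial cluster correction.

The contrast recovers the injected frontocentral theta generator as a
positive cluster over the frontal part of the grid (already visible at
n=5 subjects with reduced permutations; the test suite verifies the
underlying localization and SnPM recovery properties).  Outputs: cluster
table (TSV) and the voxel-wise t map as NIfTI in MNI space.
"""

import argparse
from pathlib import Path

from orfi_eeg import pipeline

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--subjects", type=int, default=22)
    ap.add_argument("--perms", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = pipeline.RunConfig(
        seed=args.seed, n_subjects=args.subjects, n_perm_source=args.perms
    )
    res = pipeline.source_stage(cfg, args.out)
    if len(res["table"]):
        print(res["table"].round(4))
    else:
        print("no significant source clusters")
    print(f"outputs -> {args.out}/source_theta_300ms_clusters.tsv, source_theta_300ms_t.nii.gz")
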