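# Methods

This note documents the models, parameter choices and numerical decisions behind
`orfi_eeg`, and what the synthetic study can and cannot show.

## Task model

A block is a fixed sequence of 240 outcome categories behind the *correct* square:
60 non-SAME outcomes (30 SIMI, 30 DIFF, randomly interleaved), each preceded by a run
of 2–6 SAME trials; run lengths are drawn uniformly on {2..6} and then repaired by
random unit moves (staying inside the bounds) until they sum to 180. The correct
square flips on the trial after every switch-signalling outcome — DIFF always, SIMI
only in condition *identical*. The task never states what a subject sees after
choosing the wrong square; we show DIFF (the unequivocal "target absent" signal) and
let the state machine treat it as a switch signal, while the scheduled SIMI/DIFF slots
stay attached to the correct square (error reveals do not consume them).

Agents follow the rule exactly except for a lapse probability (uniformly random
choice, default 0.02) and a perseveration probability (repeating the old square when
a switch was signalled, default 0.07). Reaction times are log-normal per
previous-outcome category (means ≈ 470/468/490 ms for SAME/SIMI/DIFF, SDs ≈ 140–160 ms),
positive and right-skewed by construction.

**Error-rate denominators.** Extinction and association error rates are reported
relative to their opportunity trials (trials following a reversal signal, and trials
following a correct stay-signalling outcome, respectively). With near-ceiling accuracy
an all-trials denominator cannot produce extinction rates of several percent while
total errors stay below ~3%, so the opportunity denominator is the only reading
consistent with the phenomenon being modelled. Under it, the default agent lands at
~97–98% accuracy, ~7% extinction and ~1% association errors.

## Spherical-head forward model

A single homogeneous sphere (radius 90 mm, center MNI (0, 0, 40) mm, conductivity
0.33 S/m) with an insulating exterior admits a closed-form surface potential for an
interior current dipole, obtained by summing the classical Legendre series with
generating functions (implementation) and verified against the truncated series
itself (test oracle, order 150, agreement ≤1e-6 relative). All potentials are
average-referenced. The montage is a 156-channel 10/05-extension template
(18 midline + 69 mirror-symmetric pairs) projected onto the sphere and frozen as an
SFP file; exact left/right symmetry is deliberate so mirror properties hold to
floating-point tolerance. The source grid is 10-mm isotropic, masked to the sphere
shrunk by 10% intersected with an MNI bounding box (~1760 voxels). Electrode
adjacency for contiguity rules is a spherical Delaunay triangulation with edges
longer than 5 cm pruned.

A multi-shell or BEM head model would change absolute potentials but not the
contracts downstream code relies on (linearity, average reference, smooth spatial
mixing), which is why the pipeline is agnostic to what stands behind the `LeadField`.

## Synthetic EEG generator

The generator is the study-conditions definition, not a tuning knob: 22 subjects,
2 conditions × 3 trial types, 56 epochs per cell, 156 channels, 1000 Hz, epochs
−700..+700 ms around outcome onset.

* **ERP components** are Gaussian-envelope dipole waveforms projected through the
  lead field; amplitudes are stated as peak scalp µV at the component's best channel.
  The default preset injects: an unspecific posterior visual response (120 ms, 3 µV);
  a frontal positivity for switch-signalling outcomes (265±45 ms, +4 µV, −1.5 µV for
  SAME, 0 for SIMI-semantical); a central negativity (350 ms, −2 µV, switch cells); and
  late central/posterior positivities (500–520 ms, +4/+2.5 µV switch vs +1.5/+0.8 µV
  otherwise). Effect sources sit radially beneath the centroid of the electrode
  cluster they drive (depth 0.55·R), so cluster-averaged waveforms retain 70–80% of
  the peak amplitude.
* **Oscillations** are amplitude-modulated sinusoidal dipoles with per-trial random
  phase, so they appear in induced power but cancel in the ERP: a frontocentral 5 Hz
  burst (Gaussian window 350±150 ms; 8 µV in switch cells vs 1.5 µV otherwise) and an
  ongoing centroparietal 20 Hz rhythm (3 µV) that dips by 1.5 µV (switch) vs 0.5 µV
  around 475 ms — a beta suppression.
* **Noise** is 1/f (exponent 1, 10 µV per channel), half channel-specific and half
  mixed through 30 random superficial dipoles, giving realistic inter-channel
  correlation for the cluster statistics. Between-subject variability is log-normal
  multiplicative amplitude jitter (SD 0.3 in log units) per component.
* **Artifacts**: 7% of epochs receive 160 µV Hanning bursts on 1–3 channels
  (flagged in the metadata, so rejection can be tested against construction);
  one randomly chosen channel per subject is flat ("disconnected") and listed as bad.

Amplitudes were chosen so that the full 22-subject chain shows the qualitative
switch-signal pattern clearly against the background; no real-data amplitude values
exist to copy. What passing tests show: the *analysis chain* detects effects with the
injected topography/latency/band structure at realistic SNR and keeps false positives
at the nominal level. What they do not show: anything about real cortical dynamics —
ocular/muscle artifact morphology, non-stationary noise, inter-individual topography
differences and volume-conduction inhomogeneities are all absent.

## Preprocessing

Fixed order: bandpass filter → average reference → rejection → interpolation →
averaging (whether rejection preceded interpolation in the original chain is
unstated; this order is our choice and rejection of a flat-plus-noise bad channel is
prevented by keeping bad channels below the rejection threshold). The filter is a
zero-phase Hamming windowed-sinc bandpass, 1–45 Hz, built as a highpass ⊛ lowpass
cascade with transition widths 1 Hz (low) and 5 Hz (high) (≈4000 taps at 1000 Hz),
applied once with reflect-limited padding and center cropping. Because the kernel
exceeds one epoch, epoched data are filtered with trials stitched end-to-end —
emulating continuous-recording filtering, with bleed between neighbours limited to
half a kernel. Rejection is strict: an epoch is dropped iff max |amplitude| > 100 µV.
Interpolation is Perrin spherical splines (stiffness 4, regularization 1e-5) via
MNE-Python. ERPs are plain per-cell trial means with **no baseline correction** —
the design can carry anticipation-related slow activity into the pre-outcome window,
and baseline subtraction would fold it into post-outcome topographies.

## Statistics

* **Mass-univariate ANOVA**: at each electrode × ms point, the 2×3 within-subject F
  from orthonormal contrast scores. Greenhouse–Geisser ε is computed from the
  contrast-score covariance and applied where Mauchly's test rejects sphericity at
  0.05 (ε is also reported raw). Numerically degenerate points (cells identical to
  float cancellation) report F = 0 rather than a 0/0 ratio. Significance masks then
  require p < 0.01 for ≥20 ms over ≥5 contiguous electrodes, with the temporal and
  spatial prunings iterated to a fixed point so every surviving sample satisfies both.
* **Cluster permutation**: two-sided paired t at α = 0.05 forms clusters of contiguous
  supra-threshold frames; the null is the distribution of the per-permutation
  *maximum* cluster size under random within-subject sign flips (default 5000);
  clusters are kept iff larger than its 95th percentile, with p = (1+#{max ≥ k})/(n+1).
  The cluster statistic is size, not mass. The same engine runs in 2-D
  (frequency × time, 4-adjacency) and 3-D (source voxels, 6-adjacency).
* **Time–frequency**: Hanning windows of 300 ms every 10 ms, frequencies 3–45 Hz on a
  1 Hz grid by direct windowed DFT. The 1 Hz grid is finer than the ~3.3 Hz window
  resolution, i.e. interpolative; neighbouring rows are correlated, which the cluster
  statistics tolerate. Power is averaged over trials first, then log-transformed and
  baseline-corrected (dB, baseline −550..0 ms); channel averaging over a cluster set
  happens after the STFT. Non-positive power is floored with a warning.
* **Beamformer**: per band, the channel cross-spectrum is averaged over the band's
  1 Hz bins and trials per 300 ms window (50 ms hop). Weights are computed once per
  band from the all-window covariance (common spatial filter — avoids window-level
  weight instability) with Tikhonov loading λ = 0.05·mean(diag). The scalar
  orientation is the smallest-eigenvalue direction of L'C⁻¹L, which maximizes
  unit-gain output power. Per-voxel log power is baseline-corrected to dB.
  Two numerical facts worth recording: (i) unit-gain output power is *minimized* at
  λ = 0 by construction, hence non-decreasing in λ (tested); (ii) raw output power is
  depth-biased toward superficial voxels, while the dB maps — the analysis quantity —
  cancel that bias voxel-wise, which is why localization is scored on dB maps.

## Problem sizes and determinism

Default statistics use 5000 permutations; the heavier self-checks use reduced but
still well-resolved sizes chosen as ordinary desk-scale simulation budgets: the null
calibration uses 1000 simulated experiments × 500 permutations (20 subjects, 701
frames of 1/f noise), localization uses 50 seeds on the 10-mm grid, and the
end-to-end recovery run uses the full 22-subject preset with 1000 permutations.
Every stochastic stage derives its sub-seed by hashing (master seed, stage name);
identical configurations re-run bit-identically, and unchanged stages are skipped via
content hashes of their parameters.

## Known limitations

Single-sphere conductor and template electrode positions (no digitized montage or
individual anatomy); no ocular/muscular artifact modelling and hence no ICA stage;
the SIMI-semantical "initially DIFF-like, then SAME-like" biphasic dynamics are not
in the default preset (its SIMI-semantical frontal component is simply absent);
source-space anatomical labels are nominal grid positions, not warped anatomy.
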