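# orfi-eeg

A tested re-implementation of a deterministic reversal-learning EEG outcome-monitoring
analysis, driven end to end by a synthetic high-density EEG generator.

## The problem

In a deterministic reversal-learning task, a participant chooses one of two squares
hiding a target object. The outcome behind the chosen square is the anticipated target
(**SAME**), a semantically similar object (**SIMI**), or an unrelated object (**DIFF**).
DIFF always instructs a switch of squares on the next trial; crucially, SIMI instructs a
switch only when the instruction defines the target as one specific object ("THIS hat",
condition *identical*) and not when any object of the category counts ("A hat",
condition *semantical*). Comparing the brain's response to *physically identical* SIMI
outcomes across the two conditions isolates outcome monitoring by behavioral relevance
rather than appearance: a frontal positivity at ~200–330 ms, later centro-posterior
positivities, a frontocentral theta power increase and a centroparietal beta
suppression, and orbitofrontal/prefrontal theta generators in source space.

Because the underlying human recordings are not publicly shareable, this package ships
a forward-modelled synthetic study with those effects injected, and re-implements the
full analysis chain as reusable, tested library code:

| module (`src/orfi_eeg/`) | what it does |
|---|---|
| `task` | block generation (240 trials: 180 SAME / 30 SIMI / 30 DIFF, SIMI/DIFF after every 2–6 SAME), rule-following stochastic agents, accuracy / extinction / association-error scoring |
| `montage`, `forward` | 156-channel 10/05 spherical montage; analytic single-sphere dipole potentials; 10-mm source grid and lead field |
| `synth` | multi-subject epoched EEG (µV, 1000 Hz, −700..+700 ms): dipole ERP components, induced oscillatory bursts, spatially mixed 1/f noise, artifact epochs, flat bad channels |
| `preprocess` | 1–45 Hz zero-phase FIR, average reference, ±100 µV rejection, spherical-spline interpolation, per-cell ERPs (no baseline correction) |
| `erp_stats` | electrode × time 2×3 repeated-measures ANOVA with Greenhouse–Geisser correction and the p<0.01 / ≥20 ms / ≥5-contiguous-electrodes extent rule; paired-t temporal cluster-permutation test (sign-flip, 95th-percentile max-cluster-size) |
| `timefreq` | 300 ms Hanning STFT (3–45 Hz, 1 Hz step, 10 ms hop), dB baseline correction (−550..0 ms), 2-D cluster statistics, topographies |
| `beamformer` | scalar minimum-variance (LCMV) beamformer on the 10-mm grid, five bands (θ 4–7, α 8–12, β1 13–20, β2 21–30, γ 31–45 Hz), dB source maps, SnPM-style spatial cluster correction |
| `pipeline` | seeded orchestration of all stages with cached outputs and a Markdown report |

The statistical core in the field's notation: at each point the cluster test forms
clusters from contiguous samples with paired |t| above the α=0.05 criterion and keeps a
cluster of size *k* iff *k* exceeds the 95th percentile of the permutation distribution
of max-cluster sizes under random within-subject sign flips; the mass-univariate map
uses the repeated-measures F with Greenhouse–Geisser–adjusted degrees of freedom
(ε from the contrast-score covariance) wherever Mauchly's test rejects sphericity.

## Worked example

```bash
python analysis/01_behavior.py --seed 1
```

prints (seed 1, 22 simulated subjects, 3 blocks per condition):

```
            subject  pct_correct  extinction_error_rate  association_error_rate
condition
identical      10.5        96.64                   7.34                    1.16
semantical     10.5        97.80                   7.09                    1.03

RT omnibus:
  main_condition: F=0.79 p=0.3853 eta2=0.036
  main_trial: F=35.72 p=0.0000 eta2=0.630
  interaction: F=0.29 p=0.7495 eta2=0.014
```

Accuracy is near ceiling; extinction errors (continuing the old square after a
reversal signal, ~7% of reversal trials) dominate association errors (switching
despite a correct "stay" outcome, ~1% of stay trials), and reaction times depend
mainly on the previous outcome type — the behavioral signature of a deterministic
reversal task. The EEG stages run the same way:

```bash
python analysis/02_erp_analysis.py --seed 1      # ERP ANOVA + cluster contrast
python analysis/03_timefreq_analysis.py --seed 1 # theta/beta power contrast
python analysis/04_source_analysis.py --seed 1   # beamformer source clusters
```

Each prints its significant clusters (window in ms, corrected p) and writes TSV
tables under `results/`.

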