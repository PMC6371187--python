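# eegworkload

A tested pipeline for theta/alpha-ratio (TAR) brain-workload analysis of
inhibition-task EEG in a three-group pre/post training study. It provides:

- **Task designs** (`eegworkload.tasks`) — exact trial sequences for the
  Stroop (8×36, alternating congruent/incongruent blocks), negative-priming
  (4×56, alternating np/control) and flanker (4×72, mixed) paradigms, with
  deterministic, seeded, exactly balanced stimulus combinations.
- **Synthetic cohorts** (`eegworkload.synth`) — lognormal reaction times with
  configurable error/omission rates, continuous 500 Hz EEG with frontal theta
  (Fz) and parietal alpha (Pz) oscillations encoding a latent TAR target per
  session, 1/f background noise and artifact transients; full three-group
  pre/post study simulation with bivariate pre–post latent draws.
- **EEG I/O** (`eegworkload.eegio`) — a lossless native container (float32
  `.dat` + JSON header + events CSV) and a read-only BrainVision
  (`.vhdr/.vmrk/.eeg`) importer for multiplexed INT_16 / IEEE_FLOAT_32 data.
- **Spectral scoring** (`eegworkload.spectral`) — zero-phase 0.1–30 Hz
  band-pass, stimulus-locked 2 s epochs (−0.5 to +1.5 s) of correct,
  artifact-free trials, edge-tapered FFT spectra zero-padded to 1024 points
  (0.488 Hz bins), theta (4–8 Hz) / alpha (8–12 Hz) band powers and
  TAR = theta_Fz / alpha_Pz.
- **Statistics** (`eegworkload.behavior`, `eegworkload.contrasts`) —
  inhibition difference scores, paired t-tests, baseline one-way ANOVA,
  planned orthogonal contrast regression of pre/post gains (AB×C and A×B,
  one-tailed), and a dependence-corrected repeated-measures Cohen's d.

## Test

```sh
python -m pytest -q tests/
```

Acceptance-level checks live in `tests/test_acceptance.py`; the two
statistical criteria (pattern recovery, type-I calibration) take ~1 minute.

## CLI

```sh
eegworkload simulate  --config config.yaml      # write a synthetic cohort
eegworkload workload  --config config.yaml      # band powers + TAR per session
eegworkload behavior  --config config.yaml      # RT/error/inhibition summaries
eegworkload contrasts --config config.yaml      # planned-contrast tables
eegworkload report    --config config.yaml      # all three analysis steps
```

A minimal config:

```yaml
seed: 17
cohort_dir: cohort
outdir: out
groups: {A: 6, B: 6, C: 6}   # simulator / attention / control
tasks: [stroop]
montage: compact              # or: standard (64 EEG + 2 eye channels)
sampling_rate: 250.0          # default 500
r: 0.7                        # assumed pre-post correlation for effect sizes
```

Outputs: `workload.csv` (subject, group, phase, task, theta_fz, alpha_pz,
tar, n_epochs), `behavior.csv`, `table1.csv` (descriptives + d),
`table2.csv` (B, SE, β, F, df, one-tailed p), `figure3_data.csv`
(group × phase means with standard errors).

## Notes

- "Equal probability" of stimulus combinations is implemented as exact
  balanced counts per block with seeded shuffling, so design invariants are
  deterministic.
- The spectral taper is a Tukey window covering 10% of the segment (5%
  raised-cosine per edge); per-bin power is normalized so an in-band
  unit-amplitude sinusoid carries ~0.5 µV² and the untapered variant
  satisfies Parseval exactly.
- Planned contrasts use one-tailed p-values in the hypothesized direction
  (training reduces workload; simulator more than attention).
- TAR defaults to the ratio of mean band powers; a mean-of-per-epoch-ratios
  variant is available via `tar_method: mean_of_ratios`.
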