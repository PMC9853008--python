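# nfasym

Simulation and offline analysis pipeline for an EEG frontal-alpha-asymmetry
neurofeedback experiment with simultaneous block-design fMRI:

- **paradigm** (`nfasym.paradigm`) — the 10-run Rest/View/Upregulation block
  timeline (130 s runs, 1300 s / 650 volumes total) with BIDS-style events
  TSV round-trip.
- **synthetic data** (`nfasym.synth`) — seeded generators for F3/F4/ECG EEG
  with a block-dependent alpha-power asymmetry, ROI-level BOLD with planted
  percent-signal-change effects and block-dependent inter-ROI correlation,
  small 4D voxel volumes with planted clusters, and paired psychometric
  score tables; whole-cohort assembly with a ground-truth manifest.
- **neurofeedback engine** (`nfasym.feedback`) — 2 s / 1 s sliding-window
  alpha log-power asymmetry `ln P(F4) − ln P(F3)`, View-block baseline,
  3-window bar smoothing with the blue/red maintain-or-increase rule, sham
  traces, and moving-average template subtraction of periodic artifacts.
- **offline EEG** (`nfasym.eeg`) — 250 Hz downsampling, 100 Hz low-pass and
  slice-harmonic band-stops, run-block asymmetry tables, condition/group
  statistics (KS normality, ANOVA, pooled two-sample t, BH-FDR), R-peak
  detection and per-block HRV (SDNN/RMSSD).
- **fMRI GLM** (`nfasym.glm`) — double-gamma HRF designs, DCT high-pass,
  Gaussian smoothing, OLS contrasts, permutation cluster-extent correction,
  and ROI percent signal change with the first-two-Upregulation-volume trim.
- **connectivity** (`nfasym.connectivity`) — blockwise Pearson/Fisher-z ROI
  correlations, 703-edge condition + group testing with BH-FDR, and the
  differential-network export.
- **stats** (`nfasym.stats`) — shared t/ANOVA/KS/BH kernel, pooled-SD
  pre/post effect sizes (with a printed-precision truncation mode), and the
  psychometric pre/post report.
- **pipeline / CLI** (`nfasym.pipeline`, `nfasym.cli`) — end-to-end
  simulate → analyze orchestration with YAML config, deterministic seeds and
  cached report bundles.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (design counts,
printed degrees of freedom, printed effect sizes, feedback-engine
properties, statistical calibration at reduced sizes, parameter recovery,
and oracle equivalence).

## CLI

```sh
nf simulate --out data/ --seed 1              # write a synthetic cohort
nf run --events data/events.tsv --eeg data/sub-01_eeg.tsv --mode real --out trace.tsv
nf eeg-analyze --data data/ --out eeg_out/
nf fmri --data data/ --out fmri_out/
nf connectivity --roi-series data/ --events data/events.tsv --out conn_out/
nf psych --scores data/scores.tsv --out psych_out/
nf report --out report/ --seed 1              # full pipeline, default config
```

`nf report --config config.yaml` accepts a YAML file overriding any of the
default config keys (`paradigm`, `cohort`, `analysis`, `seeds`).

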