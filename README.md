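# eegattn

Four-level EEG attention-state recognition as a tested, reusable pipeline:

- **simulate** — synthetic multi-subject, two-session EEG cohorts (10-channel
  10–20 montage, 512 Hz) whose four states encode an attention gradient:
  the β band-power fraction decreases and the θ+α fraction increases from
  high attention (state 1) to the non-externally-directed state (state 4).
  Includes questionnaire screening emulation and artifact injection.
- **preprocess** — zero-lag FIR band-pass (0.5–30 Hz), automated
  amplitude-threshold bad-segment rejection, and 4-s / 2-s-overlap
  sliding-window segmentation.
- **features** — ten features per channel: rectified average, maximum, peak
  difference, RMS, standard deviation, margin factor, sample entropy
  (Chebyshev, m=2, r=0.2·σ), and θ/α/β wavelet-packet band-energy ratios
  (periodized orthogonal db8 tree, level 7); 100-dimensional feature-major
  vectors on the default montage.
- **selection** — four strategies over the ten feature groups: chi-square
  and mutual-information filter rankings with a top-k sweep, an L1/tree
  embedded method, and the sequential-forward-selection wrapper with a
  strict-improvement rule.
- **evaluation** — pooled 60/20/20 stratified SVM (RBF) evaluation,
  per-subject session-holdout (train session 1, test session 2), and the
  paired t-test / Shapiro–Wilk before-vs-after comparison.
- **fixtures** — the published per-subject sample sizes, single-feature
  accuracies, selection step log, and before/after accuracy table ship as
  package data and can be replayed deterministically.

EDF read/write and the wavelet-packet transform are implemented in-package
(no EDF or wavelet third-party dependency is required).

## CLI

```bash
eegattn simulate --subjects 4 --duration 60 --seed 0 --out cohort/
eegattn features cohort/manifest.tsv --out features.csv
eegattn select features.csv --method sfs --out selection.json
eegattn train features.csv --groups F7,F5,F4,F1,F6
eegattn evaluate features.csv
eegattn replay-table6     # deterministic selection replay
eegattn replay-table7     # paired before/after statistics
eegattn run-all --config config.yaml --out run/
```

`run-all` executes simulate → preprocess → features → select → evaluate and
persists every artifact (EDF cohort + TSV manifest, CSV feature table, JSON
selection result and evaluation report). A YAML config drives all stages;
every stage is reproducible from (config, seed).

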