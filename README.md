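# bpfuse

Multi-encoder cross-sequence-attention fusion for patient-level prostate
cancer presence classification from bi-parametric MRI (T2-weighted,
high-b-value DWI, ADC map) plus clinical variables (age, PSA, PSA density).

The package implements, end to end, on a self-contained numpy stack:

- **Data model** — case containers for co-registered sequence volumes,
  gland masks and clinical records; NIfTI IO (DICOM series optional via
  `pydicom`); deterministic class-stratified cohort splits.
- **Preprocessing** — resampling to a common voxel spacing (default
  3.0/0.5/0.5 mm), fixed central crop (default 32×224×224), per-image
  min-max normalization, prostate-volume and PSA-density computation, and
  training-cohort [-1, 1] clinical scaling.
- **Architectures** — a 3D VGG-style encoder (stage widths
  [64, 128, 256, 512], blocks [1, 2, 3, 4], global max+average pooling to a
  512-d vector) shared by three families: `3ch` (channel-stacked single
  encoder), `me` (one encoder per sequence, feature concatenation, 1539-d
  fused vector with clinical variables) and `meca` (`me` plus a multi-head
  cross-sequence attention module, H=2 heads, with cascading head updates).
  The networks run on a small reverse-mode autodiff engine (`bpfuse.nn`)
  written on numpy — no deep-learning framework required — with
  finite-difference gradient tests.
- **Training** — Adam (default lr 3e-5) with L1/L2 penalties (3e-5),
  binary cross-entropy, flip/rotation augmentation applied identically to
  the three sequences of a case, validation-AUC checkpoint selection.
- **Evaluation** — Mann-Whitney AUC, prevalence-parameterized PPV/NPV with
  closed-form prevalence inversion, percentile-bootstrap confidence
  intervals, paired DeLong AUC comparisons.
- **Fairness** — stratified per-subgroup evaluation (PSA risk bands, four
  age schemes, provider, field strength, manufacturer) with suppression of
  under-sized strata and tiered significance markers.
- **Phantom generator** — synthetic bpMRI cohorts with the canonical lesion
  contrast signature (dark on T2w, bright on high-b DWI, dark on ADC),
  single-modality distractor nodules that bound what any one sequence can
  achieve, and label-correlated clinical variables; everything the tests
  and benchmarks need is generated programmatically.

## CLI

```bash
bpfuse generate --config cfg.yaml --out data/          # phantom cohort
bpfuse preprocess --config cfg.yaml --data data/ --out prep/
bpfuse train --config cfg.yaml --data data/ --out run/ # all families, shared split
bpfuse evaluate --config cfg.yaml --scores run/ --out eval/
bpfuse fairness --config cfg.yaml --scores run/ --clinical data/clinical.csv --out fair/
bpfuse reproduce-tables                                # predictive-value checks
```

Configuration is YAML over defaults (see `bpfuse.config`); `profile: full`
restores the full-scale architecture and optimizer settings, the default
`desk` profile runs everything CPU-sized. Every command writes its
resolved config next to its outputs.

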