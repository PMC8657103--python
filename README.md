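# lesionkinetics

Lesion-level evaluation of volumetric response to immune-checkpoint-inhibitor
therapy, as a reusable pipeline:

* **Rule engine** (`lesionkinetics.response`) — three-timepoint eligibility,
  tumor-growth-kinetics (TGK) rates/ratio, the volumetric hyperprogression
  call (HPDv: TTF < 2 months, TGK ratio ≥ 2, volume increase ≥ 50%), the
  Nelson ±25% volumetric response category, and the patient-level
  dissociated-response (DR) classification (progression in one organ plus
  partial response in a different organ).
* **Histogram radiomics** (`lesionkinetics.features`) — 20 first-order
  intensity features (energy, entropy, percentiles incl. 2.5/97.5,
  uniformity, RMS, skewness, Pearson kurtosis, …) plus volume and a 2.5D
  area from masked HU patches, with fixed-bin-width (default 25 HU,
  min-anchored) discretization.
* **Clustered statistics** (`lesionkinetics.stats`) — skewness-minimizing
  feature transforms (log / sqrt / cbrt, cube for signed features, ×1000
  pre-scale for unit-interval features), univariate GEE screening
  (p < 0.1), per-organ multivariable logistic GEE with exchangeable working
  correlation and backward elimination, Mann–Whitney AUC with DeLong CIs,
  and Kaplan–Meier + log-rank survival comparison of DR vs non-DR.
* **Synthetic cohorts** (`lesionkinetics.synthetic`) — a seeded simulator
  whose HPDv labels are drawn from a logistic model with organ-specific
  effects and a patient random intercept, then back-solved into volume
  series the rule engine reproduces exactly; plus a deterministic fixture
  cohort (196 patients / 621 lesions) whose classifier-derived accounting
  matches the reference marginals (147 HPDv / 349 non-HPDv / 125 excluded,
  54 DR / 142 non-DR).
* **Pipeline + CLI** (`lesionkinetics.pipeline`, `lesionkinetics.cli`).

## CLI

```bash
lesionkinetics fixture  --out fixture/                 # deterministic reference cohort
lesionkinetics simulate --seed 7 --out sim/            # configurable synthetic cohort
lesionkinetics validate --lesions fixture/lesions.csv --patients fixture/patients.csv
lesionkinetics classify --lesions fixture/lesions.csv --patients fixture/patients.csv --out run/
lesionkinetics features --patches patches/ --out features.csv
lesionkinetics fit      --features features.csv --classifications run/classifications.csv --out models.json
lesionkinetics survival --patients fixture/patients.csv --dr run/patients_out.csv --out logrank.json
lesionkinetics run      --config run.yaml              # full pipeline from YAML
```

Input contract: `lesions.csv` with columns `patient_id, lesion_id, organ
(lung|bone|lymph_node|liver|other), timepoint (pre_baseline|baseline|
follow_up), scan_date (day integer), volume_mm3` (empty = absent), and
`patients.csv` with `patient_id, ttf_days, os_days, os_event (1=death,
0=censored)`. Patches are NIfTI (`.nii`/`.nii.gz`) or NRRD image/mask
pairs named `<lesion_id>_image.*` / `<lesion_id>_mask.*`.

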