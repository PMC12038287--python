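# qtalert

An end-to-end, tested pipeline for evaluating an alert-based clinical
decision support (CDS) tool for drug-induced long-QT syndrome (diLQTS),
exercised against a fully synthetic EHR cohort with known ground truth.

The pipeline covers:

- **`qtalert.synthetic_ehr`** — a schema-complete synthetic EHR generator
  (patients, encounters, ECGs, medication orders/administrations, alerts,
  labs, diagnosis/medication code lists) with configurable effect sizes and
  a ground-truth registry for parameter-recovery testing.
- **`qtalert.ecg_qtc`** — QTc under Bazett and QRS-adjusted Fridericia
  corrections, pre/post-exposure aggregation, and diLQTS adjudication
  (max post QTc ≥ 500 ms, or an increase of more than 60 ms over the
  pre-exposure maximum).
- **`qtalert.alert_cohort`** — the interruptive-alert firing rule (any prior
  Bazett QTc ≥ 500 ms), one index event per (encounter, culprit medication),
  provider-action dichotomization, 48 h/72 h order/administration compliance
  with four missingness-recode rules, covariates, outcomes, and CDS-era
  classification by medication-specific deployment month.
- **`qtalert.comorbidity_clusters`** — one-hot encoding over demographics
  plus the top-500 diagnosis and top-500 medication codes, K-means with
  Hamming distance (majority-bit centroids), elbow-based k selection.
- **`qtalert.cohort_summaries`** — descriptive tables, standardized mean
  differences, population-standardized odds ratios, chi-square/ANOVA group
  comparisons.
- **`qtalert.outcome_models`** — marginal logistic and Poisson GEE models
  (exchangeable working correlation within patients, robust SEs), joint
  Wald tests, and predictive margins by marginal standardization.

## CLI

The stages chain through flat CSV files:

```bash
qtalert simulate --seed 1 --n-patients 5000 --out sim/
qtalert qtc      --in sim/ecgs.csv --method both --out ecgs_qtc.csv
qtalert cohort   --data sim/ --post-window-h 1 --out events.csv
qtalert cluster  --data sim/ --events events.csv --k 4 --seed 42 --elbow --out clusters.csv
qtalert summarize --events events.csv --clusters clusters.csv --out tables/
qtalert model    --events events.csv --clusters clusters.csv --suite alert --out report/
```

`simulate` also writes `ground_truth.json` (configured effect sizes,
implied marginal odds ratio, injected-discrepancy counts) next to the data.
`cohort` emits a recode-audit log with counts per missingness reason.
Model suites: `alert`, `action`, `era`, `dilqts`.

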