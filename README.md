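# tabsafe

Toolkit for generating, vetting and releasing **privacy-preserving
synthetic tabular health data**. It targets the situation biobanks and
clinical registries face: cohort tables that mix continuous
measurements, calendar dates, binary and categorical variables, carry
per-column missingness anywhere from under 1% to 90%, and cannot be
shared in raw form. `tabsafe` provides the scaffolding a deep
generative model needs around it — and lightweight reference generators
so the whole workflow runs without one.

## What's inside

* **Bidirectional preprocessing** — dates become day counts from a
  reference date; continuous/date columns are median-imputed and mapped
  through a strictly monotone empirical-quantile transform onto [0, 1],
  each accompanied by a binary missingness indicator; categoricals are
  one-hot encoded with an explicit `Unknown` level. Every step is
  invertible: `inverse_transform` restores types, labels, dates and
  missing cells exactly. A simpler constant-imputation (−1) variant is
  included for low-missingness tables.
* **Correlation- and distribution-aware losses** — auxiliary penalties
  for generative training:
  `L_cor = 2/(m(m−1)) Σ_{j<k} (g_jk − g̃_jk)²` on pairwise sample
  correlations, and
  `L_dis = (1/m) Σ_j Σ_{h≤H} (1/h)(1 − (S̃_j⁽ʰ⁾+ε)/(S_j⁽ʰ⁾+ε))²` on
  stabilised moment ratios, combined as `base + α·L_cor + β·L_dis`.
  A Gaussian-copula sampler and a greedy loss-guided refiner serve as
  desk-scale reference generators.
* **Adaptive k-anonymity binning** — aggregate views where *every*
  attribute is treated as a quasi-identifier: a greedy filter finds the
  rarest value, columns are coarsened through declared hierarchies
  (built-ins for birth year and clinical BMI classes) or removed until
  an exhaustive brute-force check proves that no filter combination
  isolates fewer than k (default 10) individuals.
* **Disclosure-risk metrics** — cluster-based k-anonymity, l-diversity,
  k-map and Δ-presence; identifiability/single-out scores;
  density-based membership inference (accuracy + AUC); zero and
  generalized correct-attribution probability; inference risk;
  linkability; and a span-based match-rate heuristic with a
  real-to-real baseline.
* **Evaluation and ranking** — per-column shape scores (1 − KS / 1 −
  TVD), pair-trend scores on encoded correlations, quality/diagnostic
  aggregates, imbalance-aware TSTR and augmentation protocols
  (weighted precision/recall/F1, G-mean), and Friedman + Nemenyi
  critical-difference ranking with a worst-rank sentinel for failed
  models.
* **Data-sufficiency analysis** — score generators on nested
  subsamples of growing size and find the knee of the curve (smoothing
  spline + kneedle) via a rank-based and a composite-score route.
* **Rejection-sampling postprocessing** — expert rules (e.g. the
  sex-specific oncology pack: cervical/placental/endometrial/ovarian
  cancers female-only, prostate/testicular male-only) filter generated
  rows, regenerating until the target size is met with zero violations.
* **Fixtures** — a seeded generator of biobank-like cohorts with
  planted correlations, a derived BMI column, sex-specific disease
  rules and configurable MCAR/MAR missingness, so everything is
  testable without access to real data.

## Worked example

The five-patient table used throughout the docs (one date column with
two missing cells, one blood-pressure column with one, one smoking
column with one):

```python
from tabsafe.fixtures import worked_example, worked_example_config
from tabsafe.preprocess import fit_transform, inverse_transform

cohort = worked_example()
enc, tf = fit_transform(cohort, worked_example_config())
print(enc.data.round(2).to_string())
```

```
   diagnosis_date_q  diagnosis_date_q_m  blood_pressure_q  blood_pressure_q_m  smoking_status=Current  smoking_status=Former  smoking_status=Never  smoking_status=Unknown
0               0.5                 0.0               0.3                 0.0                     0.0                    1.0                   0.0                     0.0
1               0.5                 1.0               0.5                 1.0                     1.0                    0.0                   0.0                     0.0
2               0.9                 0.0               0.9                 0.0                     0.0                    0.0                   0.0                     1.0
3               0.1                 0.0               0.1                 0.0                     0.0                    0.0                   1.0                     0.0
4               0.5                 1.0               0.7                 0.0                     1.0                    0.0                   0.0                     0.0
```

Patients 2 and 5 were missing their diagnosis date, so both flags are 1
and both received the median date — the same quantile level 0.5 as
patient 1, whose observed date *is* the median. Patient 3's missing
smoking status becomes the `Unknown` one-hot level. Blood pressures
95 < 120 < 130 (imputed median) < 140 < 180 map to monotonically
increasing quantiles. `inverse_transform(enc, tf, config)` restores the
original table, missing cells included.

End-to-end on a synthetic cohort from the command line:

```bash
tabsafe fixture --n 1000 --seed 1 --out cohort.csv --config-out study.yaml
tabsafe run --config study.yaml --in cohort.csv --outdir run1 --seed 1
```

which writes the transform, the synthetic table, similarity and privacy
reports, and a manifest with per-artifact digests.

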