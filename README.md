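# irindices

Surrogate insulin-resistance indices, NCEP ATP III metabolic-syndrome
classification, and population-specific Youden-optimal screening cutoffs.

Fasting-insulin assays are costly and poorly standardised, which limits
HOMA-IR as a screening tool for insulin resistance and metabolic syndrome
(MetS) in primary care.  Lipid-based surrogates need only a fasting lipid
profile, glucose and anthropometry:

- **HOMA-IR** = insulin (μIU/mL) × glucose (mmol/L) / 22.5
- **TyG index** = ln(TG × FPG)/2, both mg/dL
- **TG:HDL-C ratio** = TG / HDL, both mg/dL
- **LAP** = (waist − 65) × TG·mmol/L in men, (waist − 58) × TG·mmol/L in women

This package computes the full index panel from raw cohort tables,
classifies MetS by the NCEP ATP III rule (Asian waist thresholds; ≥ 3 of
5 criteria), and derives cutoffs for each index by maximising Youden's
J = sensitivity + specificity − 1 on the empirical ROC curve, reporting
AUC, sensitivity, specificity, PPV and NPV at the selected threshold.
A calibrated synthetic-cohort generator (two-group Gaussian-copula
mixture over correlated anthropometry and fasting labs) makes the whole
pipeline runnable and testable without patient data.

It is aimed at clinical epidemiologists evaluating screening markers in
their own populations: published cutoffs travel poorly across ethnic
groups, and the point of the machinery here is to re-derive them locally.

## Worked example

```sh
irindices run --seed 1 --output-dir results/
```

simulates the default 192-subject cohort (70 men / 122 women, planted
MetS prevalence 57/192), computes the panel, classifies MetS, and prints
the cutoff table it writes to `results/cutoffs.csv`:

```
        index  optimal_cutoff  sensitivity_pct  specificity_pct  ppv_pct  npv_pct  youden_j   auc  tp  fp  tn  fn   n  n_pos
      homa_ir            1.44             75.4             81.1     67.1     86.6      0.56 0.846  49  24 103  16 192     65
          tyg            4.66             87.7             84.3     74.0     93.0      0.72 0.906  57  20 107   8 192     65
  tg_hdl_male            3.65             73.7             88.9     73.7     88.9      0.63 0.889  14   5  40   5  64     19
tg_hdl_female            2.64             84.8             80.5     70.9     90.4      0.65 0.879  39  16  66   7 128     46
          lap           38.41             93.8             82.7     73.5     96.3      0.77 0.927  61  22 105   4 192     65
```

Each row is one index: the Youden-optimal threshold (e.g. flag TyG ≥ 4.66),
its diagnostic metrics at that threshold, the AUC of the whole curve, and
the confusion counts.  TG:HDL is derived per sex because HDL levels differ
systematically between men and women; the other indices are pooled.  LAP
discriminates best (AUC 0.93) and HOMA-IR worst (0.85) on this cohort —
the ordering reported for South Indian adults.  The run also writes
`indices.csv`, `classification.csv`, `group_comparison.csv`,
`correlations.csv`, `trend_by_bmi.csv` and `roc_points.csv` (plus the
simulated `cohort.csv`/`truth.csv`), all reproducible byte-for-byte from
the same seed.

The same analysis on your own data:

```sh
irindices run --input cohort.csv --output-dir results/
```

where `cohort.csv` has columns `id, sex, age, height_cm, weight_kg,
waist_cm, hip_cm, sbp_mmhg, dbp_mmhg, fpg_mgdl, insulin_uiu_ml, tc_mgdl,
hdl_mgdl, tg_mgdl` (optional `ldl_mgdl`; blank cells are missing).

From Python, the estimators compose with scikit-learn:

```python
from irindices import (InsulinResistanceIndices, ATPIIIClassifier,
                       YoudenThresholdClassifier, simulate_cohort, default_config)

cohort, truth = simulate_cohort(default_config(seed=1))
panel = InsulinResistanceIndices().fit(cohort).transform(cohort)
mets = ATPIIIClassifier().fit().predict(cohort)
clf = YoudenThresholdClassifier().fit(panel["tyg"], mets)
print(clf.cutoff_, clf.auc_)   # 4.66..., 0.906...
```

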