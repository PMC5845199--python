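# kdscore

Point-based prediction scores for intravenous-immunoglobulin (IVIG)
resistance in Kawasaki disease, with the statistics needed to validate
them on a cohort.

About 10–20% of children with Kawasaki disease fail first-line IVIG
(persistent or recrudescent fever ≥ 36 h after the infusion) and face
an elevated risk of coronary artery abnormality, so clinicians want to
flag likely non-responders from admission data.  `kdscore` implements
six published bedside scores — **Kobayashi**, **Egami**, **Sano**,
**Formosa**, **Kawamura** (the NLR ≥ 3.83 ∧ PLR ≥ 150 combination
rule) and a five-criterion Chinese single-center model (`ours`) — and
everything needed to evaluate them:

- a harmonized patient data model with canonical lab units
  (CRP mg/L, TB µmol/L, PLT 10⁹/L, …), unit conversion, CSV I/O with
  explicit per-column unit declarations, and first-class missing data;
- high/low-risk stratification with principled handling of
  unclassifiable patients (a patient is *indeterminate* only when the
  missing values could actually change the classification);
- diagnostic accuracy: 2×2 tables, sensitivity/specificity/PPV/NPV as
  exact ratios with Wilson 95% CIs, tie-corrected rank ROC AUC
  (AUC = P(resistant patient outscores responsive one, ties ½)) with
  DeLong 95% CIs, and printed-style half-away-from-zero rounding of
  exact rationals;
- resistant-vs-responsive cohort description (median (Q1,Q3) +
  Mann–Whitney; n (%) + chi-square/Fisher with the expected-count < 5
  switch);
- a seeded synthetic cohort generator calibrated to the
  group-conditional statistics of a real 504-patient validation cohort
  (5% resistance incidence), so the whole pipeline is testable without
  patient data.

## Worked example

Score a synthetic cohort end to end:

```bash
kdscore simulate --n 1000 --seed 7 --kawamura-missingness --out cohort.csv
kdscore evaluate cohort.csv --out run
cat run/table3.csv
```

which prints (exactly reproducible from the seed):

```
model,tp,fp,fn,tn,n_excluded,sensitivity,specificity,ppv,npv,auc,auc_95ci
kobayashi,42,324,10,624,0,0.81,0.66,0.11,0.98,0.80,0.74-0.86
egami,16,92,36,856,0,0.31,0.90,0.15,0.96,0.72,0.65-0.78
kawamura,22,197,23,605,153,0.49,0.75,0.10,0.96,0.65,0.57-0.73
sano,13,11,39,937,0,0.25,0.99,0.54,0.96,0.76,0.71-0.82
formosa,38,468,14,480,0,0.73,0.51,0.08,0.97,0.64,0.57-0.72
ours,33,231,19,717,0,0.63,0.76,0.13,0.97,0.78,0.72-0.84
```

Reading the Kobayashi row: of the 1000 patients, 42 resistant children
were correctly flagged high risk (tp) and 10 missed (fn), giving
sensitivity 0.81; 324 responsive children were over-flagged (fp),
giving specificity 0.66.  PPV is low (0.11) because resistance is rare
(~5%), while NPV is correspondingly high.  The `auc` column is the
rank AUC of the integer score over all thresholds.  The Kawamura row
excludes the 153 patients whose lymphocyte counts the simulation
withheld (the `--kawamura-missingness` preset emulates the ~15%
differential-count gap seen in practice); counts always conserve:
22+197+23+605+153 = 1000.  `run/table2.csv` holds the
resistant-vs-responsive comparison table and `run/report.json` the
full machine-readable report.

The published validation metrics of all six models can be recomputed
from the built-in reference counts:

```bash
kdscore reproduce-table3
```

```
model,tp,fp,fn,tn,n_excluded,sensitivity,specificity,ppv,npv
kobayashi,18,184,7,295,0,0.72,0.62,0.09,0.98
egami,11,88,14,391,0,0.44,0.82,0.11,0.97
kawamura,10,140,11,267,76,0.48,0.66,0.07,0.96
sano,5,43,20,436,0,0.20,0.91,0.10,0.96
formosa,17,248,8,231,0,0.68,0.48,0.06,0.97
ours,18,120,7,359,0,0.72,0.75,0.13,0.98
```

As a library:

```python
from kdscore import builtin_models, score_patient, PatientRecord, LabPanel, ClinicalSigns

patient = PatientRecord(id="p1", age_months=5, signs=ClinicalSigns(rash=True),
                        labs=LabPanel(alb=33.0, neut_pct=82.0))
result = score_patient(builtin_models()["ours"], patient)
print(result.total_points, result.risk_class)   # 6 high
```

## Layout

- `kdscore.cohort` — data model, validation, unit-aware CSV I/O
- `kdscore.units` — analyte unit conversions
- `kdscore.scoring` — the six models, rule engine, YAML model files
- `kdscore.diagnostics` — 2×2 metrics, Wilson, rank AUC, DeLong, rounding
- `kdscore.compare` — group-comparison tables
- `kdscore.simulate` — calibrated synthetic cohorts
- `kdscore.pipeline` / `kdscore.cli` — end-to-end runs and the `kdscore` CLI

See `docs/methods.md` for the statistical conventions, generator
design and known limitations.
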