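# appendiscore

Clinical decision rules for acute appendicitis — the **Alvarado**, **AIR**
(Appendicitis Inflammatory Response) and **RIPASA** scores — together with
everything needed to evaluate and audit a diagnostic-accuracy study of
them: 2×2-table metrics against the histopathology gold standard,
ROC/AUC, score correlations, an integer confusion-matrix reconstruction
engine for published rounded tables, and a seeded synthetic
appendectomy-cohort generator.

It is written for biostatisticians and clinical researchers who work with
score-comparison studies: to apply the three rules reproducibly to
patient-level data, to check whether a published accuracy table is
internally consistent, and to test evaluation pipelines without access to
patient data.

## The rules and the metrics

Each score is an additive rule over symptoms, signs and labs:
Alvarado ∈ {0,…,10} (positive if > 7), AIR ∈ {0,…,12} (positive if > 5),
RIPASA ∈ {1.5, 2.0, …, 16.0} (positive if ≥ 7.5).  Against histopathology
(disease-positive = any appendicitis; negative appendectomy =
disease-negative) the package computes

    Se = TP/(TP+FN)        Sp = TN/(TN+FP)       Acc = (TP+TN)/n
    PPV = TP/(TP+FP)       NPV = TN/(TN+FN)
    PLR = Se/(1−Sp)        NLR = (1−Se)/Sp
    AUC = P(score⁺ > score⁻) + ½·P(tie)   (trapezoid ≡ Mann–Whitney)

The reconstruction engine inverts a published row: given printed Se/Sp
and the cohort marginals (n₊, n₋), it enumerates all integer 2×2 tables,
keeps those that reproduce the printed values at their display precision,
and re-derives every other printed cell — a granularity audit for
diagnostic-accuracy tables.

## Worked example

```python
from appendiscore import *

p = PatientPresentation(
    age_years=22, sex="male", migratory_rif_pain=True, anorexia=True,
    nausea=True, vomiting=False, rif_pain=True, rif_tenderness=True,
    rebound_tenderness=True, guarding_grade="light", rovsing_sign=False,
    temperature_c=37.9, wbc_e9_per_L=13.2, pmn_percent=78.0,
    crp_mg_per_L=24.0, urinalysis_negative=True, symptom_duration_h=20,
    foreign_national=False,
)
for f in (alvarado_score, air_score, ripasa_score):
    r = f(p)
    print(f"{r.system:9s} score={r.score:<5} band={r.band:<17s} positive={r.positive}")
```

    alvarado  score=10    band=likely            positive=True
    air       score=6     band=suspected         positive=True
    ripasa    score=13.0  band=diagnosis         positive=True

This patient exceeds all three study cutoffs: every Alvarado item is
present (10/10), the AIR score sits just above its cutoff at 6 (light
peritonism, one point each for the WBC and CRP bands), and RIPASA reaches
13.0, inside its "appendicitis diagnosis" band.

Auditing a published row (here RIPASA at cutoff ≥ 7.5 in a cohort with
121 histopathology-positive and 11 negative appendectomies):

```python
row = ReportedRow("ripasa", ">=7.5", "96.7", "72.7", n_pos=121, n_neg=11,
                  ppv="97.5", npv="66.7", plr="3.54", nlr="0.05", accuracy="94.6")
rep = audit_row(row)
```

    unique matrix: tp=117 fp=3 fn=4 tn=8
      ppv       printed=97.5    recomputed=97.500  match
      npv       printed=66.7    recomputed=66.667  match
      accuracy  printed=94.6    recomputed=94.697  near_miss (delta +0.1)
      plr       printed=3.54    recomputed=3.545  near_miss (delta +0.01)
      nlr       printed=0.05    recomputed=0.045  match

Exactly one integer table is consistent with the printed Se/Sp.  PPV,
NPV and NLR check out at display precision; the printed accuracy and PLR
are each one unit low in their last digit — both exactly what truncation
(rather than half-up rounding) of the recomputed values produces, so the
row is arithmetically coherent up to rounding dialect.

The same machinery is scriptable from the shell:

```
appendiscore simulate --seed 1 --n 132 --out cohort.csv
appendiscore score    --system all --in cohort.csv --out scores.csv
appendiscore evaluate --in cohort.csv --out report.json
appendiscore audit    --row '{"system":"alvarado","cutoff":">7","sensitivity":"88.4",
                              "specificity":"63.6","n_pos":121,"n_neg":11}' --out audit.json
appendiscore run      --simulate --n 20000 --seed 1 --out report.json
```

## Synthetic cohorts

`default_params()` describes a 132-patient appendectomy series
(prevalence 121/132, histology split 92/4/25, sex ratio 79:53, age ~
truncated normal(24, 11.6) on [9, 70]); feature distributions conditional
on disease status were calibrated once, with the packaged `calibrate`
routine, so that each score's sensitivity/specificity at its study cutoff
matches published operating characteristics in expectation.  A shared
latent severity factor induces realistic correlation between the scores.
Cohorts are bit-identical for a given seed.  See `docs/methods.md` for
the model, its assumptions and its limits.

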