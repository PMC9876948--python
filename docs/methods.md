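# Methods

## The scoring rules

All three scores are additive clinical decision rules for suspected acute
appendicitis, evaluated against histopathology of the resected appendix as
the gold standard (any appendicitis — acutely inflamed, gangrenous or
perforated — is disease-positive; a histologically normal specimen is a
"negative appendectomy" and counts as disease-negative).

| system | items | range | study cutoff |
|---|---|---|---|
| Alvarado | migratory pain 1, anorexia 1, nausea 1, RIF tenderness 2, rebound 1, elevated temperature 1, leukocytosis 2, left shift 1 | 0–10 | positive if > 7 |
| AIR | vomiting 1, RIF pain 1, graded peritonism 1–3, T > 38.5 °C 1, PMN band 1–2, WBC band 1–2, CRP band 1–2 | 0–12 | positive if > 5 |
| RIPASA | sex, age, RIF pain, migration, anorexia, nausea/vomiting, duration, RIF tenderness, guarding, rebound, Rovsing, fever band, leukocytosis, negative urinalysis, foreign nationality | 1.5–16.0 (0.5 lattice) | positive if ≥ 7.5 |

Decisions taken where the published tables are loose:

* **Alvarado thresholds.** "Elevated temperature", "leukocytosis" and
  "left shift" are implemented with the classical thresholds T ≥ 37.3 °C,
  WBC ≥ 10×10⁹/L and PMN ≥ 75 %; all three are `ScoringConfig` fields, so
  alternative conventions are directly testable.
* **AIR bands.** Published AIR band listings often skip score 8
  ("5–7 suspected, 9–12 high"); the original AIR definition places 8 in
  the intermediate group and that is what `air_band` does.  The lab bands
  are half-open ([70, 85) % PMN → 1, [85, ∞) → 2; likewise WBC at 10/15
  and CRP at 1/5 mg/L) so every value maps to exactly one band.
* **AIR peritonism.** Our record distinguishes a rebound-tenderness flag
  from the graded muscular defense; the AIR grade is the guarding grade
  when present, otherwise isolated rebound counts as the light grade.
* **RIPASA details.** Fever scores only on the open interval
  (37, 39) °C, so warming a febrile patient past 39 °C removes exactly one
  point (banded by design, deliberately non-monotone).  Exactly 48 h of
  symptoms takes the longer-duration weight 0.5.  Any guarding grade above
  none earns the single guarding weight 2.0.  The nominal total is
  sometimes printed as 17.5; with the mutually exclusive sex/age/duration
  categories the reachable maximum is 16.0, and the floor is 1.5.
  A score of exactly 7.5 opens the "high probability / prepare for
  appendectomy" band, hence the inclusive cutoff (a strict variant is a
  config switch).
* **Missing data are an error.** Scores are decision rules; silently
  imputing a missing field corrupts downstream accuracy estimates, so
  validation is strict and aggregated per CSV row.

## Accuracy evaluation

`diagnostics` computes the standard 2×2-table summaries (sensitivity,
specificity, PPV, NPV, accuracy, PLR, NLR), an empirical ROC over all
distinct thresholds with trapezoidal AUC (equal to the Mann–Whitney
statistic with ties half-weighted), paired AUC differences, and Pearson
correlations between raw scores.  Percentages are carried at full
precision; display rounding (half-up; 1 dp for percentages, 2 for ratios,
3 for AUC) happens only at render time.  Empty denominators (PPV with no
positive calls, PLR at specificity 1, NLR at specificity 0) are reported
as undefined, never as silent infinities.

The only significance machinery is a seeded paired percentile bootstrap
for AUC differences (default 2,000 resamples; degenerate resamples that
lose a disease class are redrawn).  No DeLong test, no confidence
intervals on the table metrics by default.

## Reconstructing published 2×2 tables

Given a published row (printed sensitivity and specificity plus the
cohort marginals n₊, n₋), `reconstruct_matrix` enumerates every
(tp, tn) ∈ {0..n₊} × {0..n₋} and keeps the matrices whose sensitivity and
specificity round (half-up) to the printed values *at each cell's printed
precision* — "25" is matched at 0 decimals, "78.03" at two.  With
marginals 121/11 the search space is 122 × 12 candidates and each of the
three bundled rows pins down a unique matrix:

* Alvarado (>7): (tp, fp, fn, tn) = (107, 4, 14, 7)
* AIR (>5): (94, 2, 27, 9)
* RIPASA (≥7.5): (117, 3, 4, 8)

`audit_row` then recomputes every other printed cell from the recovered
matrix.  A cell that agrees at display precision is a *match*; one off by
at most two units in the last printed digit is a *near-miss* (with the
signed Δ and the value under every rounding dialect — half-up, half-even,
truncation — reported); anything further is *impossible*.  For the
bundled rows, all cells match except three one-unit near-misses, each of
which the truncation dialect reproduces exactly: Alvarado accuracy
(114/132 = 86.36 → printed 86.3), RIPASA accuracy (125/132 = 94.70 →
printed 94.6) and RIPASA PLR (exact 3.545 → printed 3.54, also the value
obtained by dividing the printed rounded percentages 96.7/27.3).  The
audit reports the dialects rather than deciding the original authors'
intent.

## Synthetic cohorts

No patient-level data are deposited with the published comparison, so the
generator emulates the cohort: disease status first
(prevalence 121/132), then features conditionally on status — Bernoulli
flags, a categorical guarding grade, truncated normals on clinical ranges
for temperature, WBC, PMN %, CRP and symptom duration.  Cohort-level
facts are fixed from the published composition: n = 132, histology split
92/4/25 among positives, sex ratio 79:53, age ~ truncated normal(24,
11.6²) on [9, 70] years.  The default fixture seed is 20220101.

**Latent severity.** One standard-normal severity variable per patient
shifts every flag's probability on the logit scale and every lab mean by
half a class SD (weight 1.0 by default).  This is the minimal departure
from conditional independence and is needed twice over: it produces the
positive score–score correlations seen in real cohorts (pure independence
given the label cannot reach them at this prevalence), and it lets a
florid minority of negative appendectomies trip all three scores at once
— without it the three published specificities (Alvarado 63.6, AIR 81.8,
RIPASA 72.7) are jointly unattainable, because a negative patient who
reaches Alvarado ≥ 8 under independence almost surely also exceeds
RIPASA 7.5.

**Calibration.** Feature-level marginals are not published, so the
class-conditional parameters are not identifiable from the published
cohort-level summaries; `calibrate` performs seeded coordinate descent (flags on the
logit scale, lab means in SD units, guarding prevalence) minimising the
summed squared deviation of Monte-Carlo sensitivity/specificity from the
target operating characteristics, using common random numbers so the
search is deterministic.  The shipped `default_params()` are the frozen
output of one such run (coarse pass, then a small-step polish at 12,000
patients per class); they were chosen over the unconstrained loss minimum
because that minimum pushed marginals to clinically silly corners.  They
are **one consistent choice, not an estimate of the study population**.
One residual quirk is documented rather than hidden: the calibrated
negative-class PMN mean (86 %) exceeds the positive-class mean (72 %) —
the optimiser's way of decoupling Alvarado's left-shift point from AIR's
two-point PMN band.

Under the defaults, a stratified cohort of 10,000 patients per class
reproduces each system's published sensitivity and specificity to within
about one point, and every Table-4-shaped cell (including the
prevalence-sensitive NPV) to within two points on a mixed 20,000-patient
cohort.  Synthetic score means land within ~1.8 points of the published
means (RIPASA is the widest at 9.9 vs 11.68 — the generator warns beyond
1.5); synthetic AUCs and correlations are *not* calibrated to the
published values and should not be read as estimates of them.

**What passing tests do and do not show.** The generator validates the
pipeline end to end and demonstrates that the published operating
characteristics are jointly realisable by an explicit generative model.
It does not model feature–feature dependence beyond the single severity
factor, time-to-surgery, or any selection into appendectomy, so agreement
on synthetic data says nothing about how the scores would perform in a
new clinical population.

## Problem sizes and numerical choices

Reconstruction is an exhaustive integer search (milliseconds).  The
Monte-Carlo checks use 10,000 patients per class (binomial SE ≤ 0.5
points), chosen so the whole suite and the acceptance script each run in
a few seconds.  Rounding uses `decimal` on shortest-repr strings, so
display values are exact; the vectorised reconstruction adds 1e-9 before
flooring to keep 0.5 ties on the half-up side under binary floats.
RIPASA cutoff comparisons use a 1e-9 tolerance so lattice scores at
exactly 7.5 compare inclusively under float arithmetic.
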