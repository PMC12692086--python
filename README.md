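# dicscore

Tools for studying how well ISTH-style disseminated intravascular
coagulation (DIC) scores predict **DIC-related bleeding in acute myeloid
leukemia (AML)**, with separate treatment of the coagulopathy-prone APL
(AML-M3) subgroup and all other (non-M3) subtypes.

Bleeding is the dominant cause of early death in AML presenting with
DIC, yet the standard ISTH overt-DIC score — points over platelet count,
D-dimer, fibrinogen and prothrombin-time (PT) prolongation, positive at
a total ≥ 5 — was designed to detect coagulopathy, not to predict
hemorrhage. `dicscore` implements the original score and eight
modifications that add lactate dehydrogenase (LDH, at a 400 or 800
threshold), hemoglobin, INR or *genetic positivity* (any recurrent
abnormality — t(8;21), t(12;21), inv(16), FLT3, NPM1, CEBPA — excluding
t(15;17) in APL), or that drop D-dimer in favor of LDH and genetics.
The package is aimed at hematology/biostatistics researchers who want to
audit these scoring rules, evaluate them against a bleeding outcome, or
prototype new modifications on simulated cohorts.

## What is inside

* **`dicscore.cohort`** — validated patient records (PT s, D-dimer
  ng/mL, fibrinogen mg/dL, platelets ×10⁹/L, LDH, Hgb g/dL, INR,
  subgroup, genetic flag, bleeding outcome) and a CSV reader/writer with
  explicit D-dimer unit handling (mg/L → ng/mL is ×1000).
* **`dicscore.scoring`** — the nine score definitions as declarative,
  JSON-exportable bin tables, with a documented boundary convention
  (threshold values fall to the lower-risk bin unless the published rule
  is ≥/≤), and a pure scoring engine.
* **`dicscore.evaluation`** — confusion-matrix metrics as exact
  rationals (sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
  positivity rate = (TP+FP)/N), the empirical ROC AUC with midrank tie
  handling (AUC = P(score_bleeder > score_non) + ½P(tie)), Youden-index
  cut-off selection (maximize sens + spec − 1), and published
  score-vs-bleeding contingency tables shipped as a packaged CSV.
* **`dicscore.simulate`** — a synthetic two-subgroup AML cohort
  generator: Bernoulli bleeding outcomes, log-normal lab marginals whose
  pooled median/IQR match the configured subgroup summaries, and
  class-conditional log-scale shifts δ = √2·σ·Φ⁻¹(AUC) so each marker
  discriminates bleeders at a configured binormal AUC.
* **`dicscore.cli`** — `dicscore simulate | score | evaluate | fixtures`.

## Worked example

```bash
dicscore simulate --seed 1 --out cohort.csv
dicscore score cohort.csv --scores ORIGINAL,M7 --out scores.csv
dicscore evaluate cohort.csv --out report/
```

`cohort.csv` holds 190 synthetic patients (61 M3, 129 non-M3) drawn from
the default study frame. A patient row and its scores look like:

```
patient_id,subgroup,pt_seconds,d_dimer,fibrinogen_mg_dl,platelet_1e9_l,ldh,...
M3-01,M3,10.899...,4182.89...,243.31...,10.67...,651.49...,...

patient_id,score_id,pt_prolongation,d_dimer,fibrinogen,platelet,ldh800,genetics,total,positive
M3-01,ORIGINAL,0,3,0,2,,,5,1
M3-01,M7,0,,0,2,0,1,3,0
```

Patient `M3-01` has a strongly increased D-dimer (>4000 ng/mL → 3
points) and platelets below 50 ×10⁹/L (2 points): total 5, overt DIC by
the original rule, but below the M7 threshold of 5 once D-dimer is
dropped (LDH 651 < 800 scores 0; the genetic flag adds 1).
`report/evaluation.json` then lists, per score and subgroup, the
confusion matrix against the simulated bleeding outcome, exact and
percent sensitivity/specificity with Wilson 95% intervals, the rank AUC
of the integer total, and per-marker univariate AUCs with Youden
cut-offs.

In Python, the packaged contingency tables reproduce the published
operating characteristics exactly:

```python
>>> from dicscore import (load_reference_contingency, expand_contingency,
...                       confusion, sensitivity, specificity)
>>> from dicscore.evaluation import percent
>>> row = load_reference_contingency().iloc[0]   # original score, non-M3
>>> cm = confusion(*expand_contingency(row.tp, row.fp, row.fn, row.tn))
>>> percent(sensitivity(cm)), percent(specificity(cm))
(76.5, 48.2)
```

i.e. the original score catches 76.5% of non-M3 bleeders but clears only
48.2% of non-bleeders; the M7 modification (drop D-dimer, add LDH ≥ 800
and genetic positivity) moves these to 82.4% and 60.7%.

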