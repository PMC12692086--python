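# Methods

## Scoring model

Each of the nine scoring systems is a sum of independent per-component
point rules applied to a single patient record at diagnosis; a system is
"positive" when the total reaches its threshold. The component rules:

| Component | Bins → points | Max |
|---|---|---|
| PT prolongation (s over 13.5) | ≤3 → 0, (3, 6] → 1, >6 → 2 | 2 |
| D-dimer (ng/mL) | <500 → 0, [500, 4000] → 2, >4000 → 3 | 3 |
| Fibrinogen (mg/dL) | ≥100 → 0, <100 → 1 | 1 |
| Platelets (×10⁹/L) | ≥100 → 0, [50, 100) → 1, <50 → 2 | 2 |
| LDH | ≥400 → 1 (variant A) or ≥800 → 1 (variant B) | 1 |
| Hemoglobin (g/dL) | ≥7 → 0, <7 → 1 | 1 |
| INR | ≤1.2 → 0, >1.2 → 1 | 1 |
| Genetic positivity | any → 1 | 1 |

Systems: ORIGINAL = the four core components, positive at ≥5 (overt
DIC). M1/M2 add LDH (400/800), M3 genetics, M4 hemoglobin, M5 INR, each
positive at ≥6. M6/M7 drop D-dimer and add LDH (400/800) + genetics,
positive at ≥5. M8 drops D-dimer and adds genetics only, positive at ≥4.
Maximum totals are therefore 8, 9 (M1–M5), 7 (M6/M7) and 6 (M8).

Design choices:

* **Boundary convention.** The published bin descriptions use strict
  inequalities on both sides, leaving exact threshold values
  unassigned. A value exactly at a threshold is assigned to the
  lower-point bin, except where the source rule is printed with ≥/≤
  (LDH, hemoglobin, INR — there the threshold itself scores as
  printed). Both stated D-dimer limits (500 and 4000 ng/mL) belong to
  the "moderate increase" bin. The convention lives in one interval
  table, is exported verbatim by `definitions_to_json()`, and is
  exercised at every boundary by the oracle grid test.
* **PT baseline.** PT prolongation is measured against the upper normal
  limit of 13.5 s (normal range 11.5–13.5 s), floored at zero. The
  baseline is a named constant and a function argument, since
  laboratories differ.
* **Units.** D-dimer is canonical in ng/mL because the score thresholds
  are stated in ng/mL while summary tables in this literature often use
  mg/L; the CSV reader takes an explicit unit flag and converts ×1000.
  LDH is carried as a bare number on the reported assay scale — the
  400/800 thresholds apply to the reported value, whose unit is
  inconsistently labelled across sources (mg/dL vs U/L).
* **Missing data.** Lab fields may be missing per record; a record is
  rejected only by scores that need the missing component (the D-dimer-
  free M6–M8 still score a D-dimer-missing record). `score_all` reports
  such failures explicitly instead of dropping rows.

## Evaluation

Score positivity is evaluated against the DIC-related-bleeding outcome,
stratified by subgroup. Sensitivity, specificity and positivity rate
are exact `Fraction`s; percentages are rounded half-up to one decimal
only at serialization. Wilson 95% intervals accompany the proportions
(reporting convenience, computed via statsmodels).

The empirical AUC uses the Mann–Whitney midrank convention (ties count
½); an all-pairs brute-force oracle in the test suite checks equality
on random cohorts. Youden cut-offs scan midpoints between adjacent
distinct observed values plus ∓∞ sentinels; the marker's risk direction
(high LDH vs low fibrinogen) is explicit configuration, never inferred,
and Youden ties break toward higher specificity, then the lower cut-off,
making the result deterministic. Strata missing an outcome class yield
flagged-undefined metrics, never silent zeros.

## Synthetic cohort generator

The generator emulates the statistical frame of a 190-patient
single-center AML cohort (61 M3 / 129 non-M3): per-stratum Bernoulli
bleeding outcomes (default prevalences 0.508 and 0.132), Bernoulli
genetic positivity (default rates 9/61 and 47/129, independent of
bleeding unless an odds-ratio knob is set), and log-normal laboratory
marginals.

For each marker the pooled subgroup summary (median, q25, q75) and a
target univariate AUC are configured; defaults transcribe the published
pooled summaries and discrimination estimates (e.g. non-M3 LDH median
478, IQR 257–868, AUC 0.756). Sampling is class-conditional with equal
log-scale variance: non-bleeders ~ exp(N(μ₀, σ)), bleeders ~
exp(N(μ₀+δ, σ)) with δ = √2·σ·Φ⁻¹(AUC) signed by the risk direction, so
the pairwise AUC equals the target exactly (binormal closed form
Φ(δ/(σ√2))). (μ₀, σ) are solved numerically so the *mixture* at the
configured prevalence matches the configured median exactly and the
natural-scale IQR width (q75−q25); with two free parameters under the
AUC constraint the individual quartiles of an asymmetric summary cannot
also be matched exactly, and median + IQR width is the fidelity
contract the tests enforce (within 2% at 10⁵ draws per stratum).

Markers are drawn independently given the outcome class; the observed
inter-lab correlation structure is unreported and not simulated, except
that INR is derived deterministically from PT as `pt_seconds / 12.5`
(normal-range midpoint, ISI ≈ 1) so PT and INR never contradict each
other. `lognormal_from_quartiles` itself is an exact quantile fit
(μ = ln median, σ = ln(q75/q25)/(2z₀.₇₅), z₀.₇₅ ≈ 0.6745).

What passing tests show — and don't: the generator reproduces marginal
summaries, per-marker discrimination and prevalences, so it validates
the scoring/evaluation machinery end to end and supports power-style
experiments on cut-off recovery. It does **not** reproduce the joint
distribution of a real cohort (no lab–lab correlations beyond PT→INR,
no treatment or time dynamics, no outcome-conditional genetic rates by
default), so composite-score AUCs measured on synthetic cohorts are
properties of the simulation, not estimates of the published
cohort-level AUCs, which cannot be reconstructed without patient-level
data.

## Numerical choices and problem sizes

* Mixture quantiles are found by `brentq` on the mixture CDF
  (tolerance 1e-12) inside a two-variable `scipy.optimize.root` solve;
  fits are cached per (marker, prevalence).
* Generation is vectorized per stratum with `numpy.random.default_rng`;
  a fixed draw order (bleeding, genetics, markers in config order, M3
  before non-M3) makes output CSVs byte-identical for a given seed.
* Test and acceptance runs use 10⁵ (or 5×10⁴ in the acceptance script)
  draws per stratum for marginal checks and 100 replicates of the
  default frame for Youden-recovery checks; these sizes put Monte-Carlo
  error well inside the asserted bands.
* Percent rounding uses decimal half-up, matching the one-decimal
  precision of the published tables.

## Known limitations

* The scoring engine accepts any finite values inside physiologic
  guards; it does not model assay detection limits or censored lab
  values.
* The equal-variance binormal model is a modelling convenience; real
  lab distributions may differ in shape between bleeders and
  non-bleeders (the config allows per-marker normal marginals only in
  the log-scale sense used here).
* Genetic positivity pools biologically distinct abnormalities into one
  flag, as the scoring rules require.
* No multivariate model fitting, DeLong AUC comparisons, or survival
  analysis; the package evaluates fixed rules.
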