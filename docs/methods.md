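# Methods

This note documents the models, rules and numerical conventions the package
implements, the design of the synthetic cohort generator, and what the
passing test suite does and does not establish about behavior on real data.

## Clinical-state labeling

Labels are computed at every unique event or treatment timestamp and carried
forward between timestamps.

**Suspected infection.** Two dialects, because the choice materially changes
which patients count as septic. *Concomitant*: an antibiotic order and a
body-fluid culture order within 24 h of each other (window configurable).
*Seymour-style*: antibiotic first with the culture within 24 h, or culture
first with the antibiotic within 72 h. In both, the reported time is the
earlier order of the qualifying pair.

**SOFA (Sepsis-3).** Each of the six organ subscores reads the *worst*
observed value over the trailing 24 h (half-open window `(t−24, t]`, so an
observation exactly 24 h old has aged out). Thresholds ship as a versioned
YAML fixture (`preshock/data/sofa_thresholds.yaml`). Conventions:

- Respiration uses PaO₂/FiO₂ evaluated at PaO₂ draw times with
  carried-forward FiO₂ (room air 0.21 when FiO₂ was never charted);
  ventilation status is not separately gated, since ventilator charting is
  outside the data model.
- Cardiovascular: MAP worst-in-window < 70 mmHg scores 1 without
  vasopressors; an active vasopressor scores 2–4 by agent-specific dose
  bands (norepinephrine/epinephrine ≤ 0.1 µg/kg/min → 3, above → 4;
  dopamine ≤ 5 → 2, ≤ 15 → 3, above → 4; dobutamine any dose → 2). A dose
  record is active from its timestamp until the next record for the same
  agent; a zero-dose record is a stop. A segment counts while it overlaps
  the trailing window.
- Renal uses creatinine only (urine-output branch omitted: bolus-charted
  urine volumes are too irregular to bin reliably).
- A missing organ input scores 0 — dysfunction is never asserted without
  evidence. (The alternative policy, carrying the last known subscore, is
  what the carry-forward window already approximates; it is not separately
  implemented.)

**Sepsis-3 states.** `sepsis` = suspected infection established and SOFA
total ≥ 2. `septic_shock` additionally requires, simultaneously:
cumulative fluid boluses ≥ 30 mL/kg over the trailing 24 h (the standard
resuscitation convention; both number and window configurable), an active
vasopressor — the operational reading of "requires vasopressors to maintain
MAP ≥ 65", chosen because onset must be computable from the record without
counterfactual blood-pressure reasoning — and carried-forward lactate
strictly greater than 2 mmol/L. Onset *t*ₒ is the first such timestamp.
The rule is evaluated pointwise; labels may revert if a condition lapses.

**Sepsis-2 states.** SIRS criteria (temperature, heart rate, respiratory
rate or PaCO₂, WBC; fixture `sirs_criteria.yaml`) are counted on *current*
carried-forward values. The sepsis and severe-sepsis states are aggregated;
shock requires hypotension (MAP < 65) despite rule-adequate fluids, or an
active vasopressor. The SOFA-vs-SIRS windowing asymmetry is deliberate:
24 h-worst scoring makes Sepsis-3 labels temporally smooth, while
instantaneous SIRS makes Sepsis-2 labels flip with each borderline vital —
the dwell-time and label-change statistics quantify exactly this, and the
test suite asserts the instability ordering on the default synthetic
cohort.

## Feature pipeline

One row per unique observation timestamp per patient; raw features carried
forward (mask recorded where no prior observation exists), SOFA-subscore
features computed as above. Rows of shock patients are truncated strictly
before *t*ₒ everywhere except positive-offset training windows in the
window sweep; evaluation never sees post-onset rows, so EWT ≥ 0 by
construction. The default feature set is the ten found most useful for
detection: lactate, cardiovascular SOFA, GCS, heart rate, PaO₂, FiO₂, BUN,
respiratory rate, respiratory SOFA, coagulation SOFA.

Normalization is z-scoring with means and *sample* SDs (ddof = 1 — the
convention is pinned because tests freeze exact values) estimated on
training patients only; zero-variance features are dropped with a warning.
Missing entries become 0 after normalization, i.e. training-mean
imputation, which keeps a linear model's contribution for an unseen feature
neutral.

Training sets: label 1 = rows of shock patients inside the closed window
`[tₒ + o − L, tₒ + o]` (default end offset o = −1 h, length L = 1 h, the
window found to detect best; the sweep utility produces the 16 candidate
sets for o ∈ {−11, …, +4}); label 0 = every sepsis-labeled row of patients
who never shocked. Leakage guards (no positive row past the window end, no
negative row from a shock patient) are asserted on every build.

## Risk models

**Lasso GLM (primary).** l1-regularized logistic regression; the strength
is chosen by 10-fold cross-validated deviance with folds split *by patient*
(row-level folds would leak within-patient correlation and flatter the
model), then refit on all training rows. Selection rule: minimum CV
deviance by default; a 1-SE rule is available and is the right choice when
a genuinely sparse/null solution matters. Reported odds ratios and 95%
bounds come from an unpenalized refit on the selected features (Wald
intervals). These are post-selection intervals without a selective-
inference correction — the conventional presentation — and should be read
as conditional on the selected set. If the refit fails (separable toy
data), penalized coefficients are reported with NaN bounds. Risk scores
always come from the penalized fit; `exp_coef` equals `exp(coef)` exactly.

**XGBoost adapter.** Delegates to `xgboost.XGBClassifier` (150 trees,
depth 3, learning rate 0.1, single-thread, deterministic seed) behind the
same `predict_risk` contract; the tree machinery is deliberately not
reimplemented.

**Cox comparator.** Lasso-penalized Cox proportional hazards (lifelines;
Efron tie handling) on per-row samples: duration = time from row to shock
onset, or to end of observation for censored rows. The penalizer is chosen
by patient-grouped cross-validated partial likelihood over a small grid.
The per-row risk is the linear predictor: the alert-score functional of the
original hazard-based comparator is not published, and the linear predictor
preserves the hazard's ROC ordering, which is all the downstream threshold
machinery uses.

## Detection and evaluation

Crossing is inclusive (*z* ≥ θ): on continuous scores the choice is
immaterial, and inclusivity makes integer-valued toy scores tie
reproducibly. Patient-level outcomes: TP = shock patient with any pre-onset
crossing, FP = non-shock patient with any crossing, FN/TN their complements.
The ROC is a function of per-patient trajectory maxima; the threshold grid
is every distinct maximum plus +∞, which makes the curve exact and lets the
test suite check it against the Mann–Whitney rank statistic. The operating
threshold minimizes Euclidean distance to (FPR 0, TPR 1), ties broken
toward lower FPR (a 1e−12 tolerance makes mathematically exact ties compare
equal in floating point).

Patient-specific PPV: detected patients are ranked by *z*_θ (first
supra-threshold value, stable sort) and split into 10 equal-count bins
(sizes differ by ≤ 1); PPV is the TP fraction per bin, computed on the
evaluation cohort since it is a test-time quantity. PPV with zero predicted
positives is reported as undefined (NaN + flag), never 0.

Bootstrap comparison resamples *patients* (not rows) with replacement,
applies the identical resample to both models (common random numbers), and
compares the replicate metric samples with a two-sided Wilcoxon rank-sum
test; degenerate single-class replicates are redrawn and counted.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
known ground truth, so every downstream stage is testable offline.

**States and physiology.** Each patient runs non-sepsis → sepsis; shock
patients continue through a deterioration ramp → pre-shock (2 h) → shock at
*t*ₒ. State-conditional means/SDs for lactate, GCS, heart rate, PaO₂ and
FiO₂ follow the published sepsis → pre-shock → shock contrast for
progressing patients; the remaining columns (MAP, respiratory rate, WBC,
platelets, bilirubin, creatinine, BUN, PaCO₂, temperature) and the
non-sepsis column are the package's own defaults, chosen once to reflect
the canonical physiology of incipient circulatory failure (falling MAP and
platelets, rising respiratory rate and renal markers) and frozen as the
study conditions. Cardiovascular SOFA is *derived* (from MAP and
vasopressors), not drawn, so its generated distribution is not matched to a
table.

**Why a ramp and patient random effects.** Two facts about real ICU series
matter for patient-level detection and are modeled explicitly:

1. physiology deteriorates *gradually* before shock — this is the premise
   that makes early warning possible — so shock patients drift linearly
   from sepsis toward pre-shock values over the 12 h before pre-shock
   entry (`deterioration_hours`, exponent configurable);
2. cross-sectional mean ± SD tables conflate between-patient heterogeneity
   with within-patient variability; treating the full SD as measurement
   noise makes every patient's 24 h-worst values saturate and drowns
   patient-level maxima in noise. Each state SD is therefore split into a
   stable per-patient offset (fraction 0.8 of the SD) plus within-patient
   noise, preserving the configured marginal mean and SD exactly.

**Moments vs physical floors.** `sample_state_vector` draws truncated
normals at ±8 SD — effectively untruncated — so configured moments are
reproduced exactly (the law-of-large-numbers tests and the acceptance
script measure this). Values are clipped into plausibility bounds only when
emitted as measurements (a charted lactate cannot be negative), and GCS is
rounded and clipped to 3–15. The emitted-scale clipping slightly shifts
cohort-level means for low-floor features; the distributional fidelity
checks target the sampler, which is the configured object.

**Treatments and onset consistency.** All patients get concomitant
antibiotic + culture orders before sepsis onset. Shock patients get two
fluid boluses totalling 40 mL/kg at *t*ₒ−3 h and *t*ₒ−1.5 h, a vasopressor
start (norepinephrine 0.05–0.3 µg/kg/min) at exactly *t*ₒ, and planted
measurements: lactate and MAP inside the pre-shock window (deterioration
triggers a lab draw, as it does clinically) and, at *t*ₒ, a lactate
truncated to > 2 mmol/L plus a MAP near the vasopressor-maintained target.
Because the vasopressor is the last condition to become true, the Sepsis-3
labeler recovers *t*ₒ exactly on generated patients — the core
generator/labeler consistency test.

**Sampling.** Observation times are independent Poisson processes at
0.5 events/h for vitals and 0.125 events/h for labs (labs 4× sparser,
mimicking ICU charting). Seeds propagate through `SeedSequence` spawning:
one config seed makes the serialized cohort byte-identical across runs.

**Direct risk-link sampler.** For parameter-recovery experiments the
modeling stage is tested in isolation: feature vectors are drawn i.i.d.
standard normal (already z-scored) and window membership follows a logistic
model with configured odds ratios per SD — lactate 5, the rest in
decreasing order of importance. This isolates estimator bias from labeling
and carry-forward effects.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: missing-not-at-random measurement (charting
frequency is outcome-independent here except for the planted pre-shock
draws), within-state autocorrelation beyond the patient offset (an optional
AR(1) flag exists, default off), treatment feedback on physiology (MAP does
not respond to the vasopressor), unit heterogeneity, multi-center drift,
artifactual outliers, and real non-progressor physiology (non-shock sepsis
patients reuse the progressors' sepsis-phase distribution). Real-data
performance claims cannot be transferred from the synthetic cohort; the
synthetic results validate the *machinery*, not clinical accuracy.

## Problem sizes and determinism

The test suite exercises: moment fidelity at n = 10⁵ draws; lactate
odds-ratio recovery at 20,000 samples (fitted 95% CI covers the configured
5.0); labeler-vs-brute-force SOFA agreement on 1,000 random timelines;
onset recovery on a 200-patient cohort (≥ 95% within one median
inter-observation interval); detection oracles on 1,000 random instances
each; and the full pipeline on a 1,000-patient cohort with a 70/30
patient split — the scale at which the package's study conditions are
defined — asserting AUC > 0.8, positive median EWT, and non-negative
rank-correlation trends for PPV-by-decile and EWT-vs-record-length. All
randomness flows from explicit seeds; every reported number is recomputed
at run time by `scripts/acceptance.py` and the suite.

## Known limitations

- Post-selection confidence intervals are not selective-inference-corrected.
- The Sepsis-3 vasopressor criterion cannot distinguish pressure support
  from other indications for vasopressors; neither can any purely
  record-driven labeler.
- The PPV-by-decile trend on a single synthetic cohort is a weak-signal
  statistic (~15 detected patients per bin at n = 1,000); it is asserted
  non-negative, not strongly positive.
- Sepsis-2 severe-sepsis organ-dysfunction subcriteria are not separately
  implemented; the aggregate sepsis/severe-sepsis state is the contract.
- The cardiovascular SOFA dose bands assume doses are recorded in each
  agent's native units; no cross-agent dose conversion is applied beyond
  the banded fixture.
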