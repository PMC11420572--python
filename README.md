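# engagekit

Quantifying long-term patient engagement with mobile-health (mHealth) apps
from raw usage logs.  Clinical apps — weight-management and
survivorship-support tools among them — log every interaction (a meal
logged, a weight entered, a message sent), yet most studies still measure
"engagement" by interview or survey.  `engagekit` computes reproducible
engagement indices directly from those logs and evaluates how well they
predict long-term use, for biostatisticians and digital-health researchers
working with per-patient event streams.

## The indices

A *session* is one calendar day with at least one app event.  Within a
fixed study window of `T` weeks (week numbering is 1-based; windows are
half-open day ranges like `[90, 180)`), each patient gets three component
indices in `[0, 1]` and their mean, the engagement index:

**Existing (web-analytics) EI**

- click depth `= |{weeks with ≥ 2 distinct menus}| / T`
- loyalty `= |{weeks with any access}| / T`
- recency `= 1 / mean(inter-visit gap in weeks)` (0 with fewer than two
  visit weeks)
- `EI = (click depth + loyalty + recency) / 3`

**New EI**

- **Menu abundancy (MI).**  Each menu's *survival time* is the number of
  days from its first in-window use until discontinuation (the start of
  ≥ 45 consecutive days without using it; 45 days is the 75th-percentile
  inter-usage gap).  The per-menu survival times form a vector `v_p`; with
  `v_min`, `v_max` the vectors of the patients with the smallest and
  largest Euclidean norm,

      MI(p) = ‖v_p − v_min‖ / ‖v_max − v_min‖, clipped to [0, 1].

- **Enriched loyalty (LI).**  `(|visit weeks| + ln(final usage week)) / T`,
  rescaled by the cohort maximum so the most loyal patient scores 1.
- **Permutation-entropy recency (RI).**  `1 − H(π) / ln(m!)`, where `H(π)`
  is the Shannon entropy of the ordinal-pattern distribution (order `m = 3`,
  delay 1) of the patient's weekly visit-count series: constant weekly
  usage gives RI = 1, erratic usage gives RI ≈ 0.
- `EI = (MI + LI + RI) / 3`, computed under three menu combinations:
  EI1 (self-logging menus), EI2 (free-version menus: meal log, exercise
  log, weight log, step count) and EI3 (all six menus).

**Evaluation.**  (a) OLS of the 6–9-month EI on the 3–6-month components
(`EI = β₀ + β₁·MI + β₂·LI + β₃·RI + ε`), scored by in-sample MSE/RMSE/R²;
(b) Cox proportional hazards for app discontinuation (last session before a
≥ 45-day all-menu gap) on the 3–6-month components, with per-component
log-rank tests at a median split.  HR < 1 means a protective index.

No public dataset has this structure, so `engagekit.simulate` generates
synthetic cohorts from engagement archetypes with known ground truth
(including each patient's true dropout week) for validation.

## Worked example

```python
import engagekit as ek

log, truth = ek.emulate_study_shape(seed=7)   # 233 patients, 540 days
results = ek.EngagementStudy(log).fit()
print(results.summary())
```

```
Engagement index comparison
===========================
patients: 233    windows: 3-6mo -> 6-9mo

Cross-window EI prediction (in-sample):
           MSE  RMSE    R2   best
model
existing 0.034 0.183 0.756  False
EI1      0.016 0.128 0.747  False
EI2      0.018 0.133 0.759   True
EI3      0.017 0.131 0.746  False

best model by R2: EI2

Usage survival from day 90 (199 discontinuations, 34 censored):
-- EI2
               hr    ci_low  ci_high         p  logrank_p
component
mi         0.8364    0.1978    3.537    0.8081  2.826e-49
li        0.00443 0.0008463  0.02319 1.394e-10  1.097e-48
ri          0.932    0.4678    1.857    0.8414     0.8838
...
```

Reading it: every index variant predicts the later window well on this
synthetic cohort, with EI2 — whose menus are the ones engaged archetypes
use habitually — edging out EI3, which dilutes the same signal with the
occasional messaging/reading menus.  In the survival arm the loyalty
component is strongly protective (HR ≪ 1, p < 0.001): patients whose
3–6-month loyalty is high keep using the app far longer.  Per-patient
component values are in `results.predictor_indices["EI2"]`:

```
               mi     li     ri     ei combination_label window_label
patient_id
P001        0.567  0.598  0.211  0.458               EI2        3-6mo
P002        0.000  0.000  0.000  0.000               EI2        3-6mo
```

The same pipeline is scriptable: `engagekit simulate --seed 7 --out
events.csv`, `engagekit ei-new --events events.csv --window 90:180
--combination EI2 --out ei.csv`, `engagekit evaluate --events events.csv
--out report/`.

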