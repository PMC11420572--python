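# Methods

This note documents the models and procedures `engagekit` implements, the
conventions chosen where the underlying definitions are open, and what the
synthetic cohorts do and do not establish.

## Sessions, windows and weekly binning

App logs rarely delimit true sessions, so a session is defined as one
calendar day with at least one event; repeated events within a day are
collapsed.  Days are offsets from each patient's own enrollment (day 0).
Study months are fixed 30-day blocks, so the windows of interest are
`[90, 180)` ("3–6 months") and `[180, 270)` ("6–9 months"), half-open.
Weeks inside a window are 1-based, `week(d) = ⌊(d − start)/7⌋ + 1`, and
every ratio uses the retrospective denominator `T = ⌈window days / 7⌉`
(the number of started weeks, identical for all patients).  Whether
windows should count from enrollment or from first app use is not fixed by
the definitions; enrollment is used.

## The existing engagement index

Click depth counts weeks with ≥ 2 *distinct* menus (breadth of use, true to
the index's page-view origin), loyalty counts weeks with any access, and
recency is the reciprocal mean gap between successive visit *weeks*.
Degenerate cases are resolved toward least engagement: a patient with
fewer than two visit weeks has no gaps and receives recency 0, so a
one-shot user is not rewarded for "never having left".  The EI is exactly
the arithmetic mean of the three components, a property the test suite
asserts patient by patient.

## The new engagement index

### Menu survival and menu abundancy

A menu's survival clock starts at its first in-window use and stops at the
last use preceding the first nonusage gap of ≥ `gap_threshold_days`
(default 45, the 75th-percentile inter-usage gap; `nonusage_gap_percentile`
reports the corresponding quantile of any cohort for auditing, but the
threshold is a configuration value, never recomputed silently).  Gaps
between successive uses and the trailing gap to the window end both count
as nonusage, so survival is always `last qualifying use − first use`; a
never-used menu survives 0 days and a single-day user survives 0 days.
The alternative convention (run to window end when never discontinued) was
considered and rejected because discontinuation is anchored to nonusage
*after* use; it remains reachable by treating the window end as a use day
upstream if ever needed.

Menu abundancy normalizes each patient's survival vector against the
cohort: the reference patients are those with minimum and maximum
Euclidean norm (ties broken by patient id for determinism), and
`MI(p) = ‖v_p − v_min‖ / ‖v_max − v_min‖`.  In two or more dimensions a
patient orthogonally far from `v_min` can exceed the denominator, so values
are clipped to `[0, 1]` with a warning counter; an all-identical cohort
makes the index undefined and yields MI = 0 for everyone, with a warning.
MI is invariant to rescaling all vectors by a positive constant, and to
translating all vectors by a constant vector whenever the norm ordering of
the reference patients is preserved (distances themselves are always
translation-invariant).

### Enriched loyalty

`raw(p) = (|visit weeks| + ln(final usage week)) / T`, with the logarithm
taken as 0 when the final usage week is ≤ 1 (so `ln` never goes negative
and a week-1-only user is not penalized below a never-user).  Because raw
values can exceed 1, every cohort is rescaled by its maximum raw value;
the most loyal patient scores exactly 1 by construction.  The rescale, like
MI, is cohort-relative and computed per window per combination — cohorts
are never mixed across windows.

### Permutation-entropy recency

The input series is the patient's weekly visit-day counts over the window
(length `T`); a daily series would be dominated by zeros while every other
index is weekly.  Ordinal patterns of order `m = 3` at delay 1 (standard
practice for short series; both configurable) are counted with ties ranked
by position — earlier index = smaller rank — which is deterministic and
seed-free, unlike noise-jitter tie-breaking.  Entropy is normalized by
`ln(m!)`, and `RI = 1 − PE` so that higher means more regular.  A series
shorter than `(m−1)τ + 1` yields RI = 0 with a flag.

Two calibrations are provided because the normalization of PE to `[0, 1]`
admits two readings: `none` (the default) uses the `ln(m!)`-normalized
entropy directly, and `truncated_normal_cdf` maps each cohort's PE values
through the CDF of a normal distribution fitted to them (moment fit) and
truncated to `[0, 1]`.  The CDF map is monotone, so patient rankings are
identical under both; a degenerate cohort (zero PE variance) falls back to
the raw values.

### Zero-activity guard

A patient with no in-window events on the active menu combination has an
all-zero weekly series — formally perfectly regular, hence RI = 1.  The
guard overrides this: such patients receive LI = 0 and RI = 0 (MI follows
the formula; the zero vector is the minimum-norm vector whenever any other
patient was active, so MI = 0 too).  An absent user must not score as
maximally engaged on any component.

## Evaluation

**Regression arm.**  The printed regression form relates a window's EI to
its own components, but the stated aim is predicting the *later* period
from the earlier one — and the same-window fit is trivially perfect because
the EI is the exact mean of its components (the test suite uses this as a
positive control: R² = 1, all slopes 1/3).  The default therefore regresses
the 6–9-month EI on the 3–6-month components; `same_window=True` reproduces
the literal form.  Fits are ordinary least squares (statsmodels); MSE, RMSE
and R² are in-sample goodness of fit — no train/test split, which is the
natural reading of a reportable R² near 0.05 for a 3-predictor model.
Shapiro-Wilk residual normality and Durbin-Watson statistics are optional
report fields, not gates.

**Survival arm.**  App-level discontinuation applies the same 45-day rule
to the all-menu session stream, scanning from the survival origin (default
day 90, the start of the predictor window; the origin is configurable since
the definitions do not fix it).  Patients with no post-origin activity get
time = 1 day, discontinued, because zero durations are invalid in partial
likelihood.  The Cox model (lifelines, Efron tie handling — day-resolution
data has many ties) enters the three components jointly by default,
matching the proportional-hazards formula; `univariate=True` fits one
component at a time for the one-at-a-time reading.  Each component also
gets a two-group log-rank test at a median split (high = strictly above
the median; the grouping rule is configurable in principle but only the
median split is implemented, as no other grouping is defined).

## The synthetic cohort generator

The generator emulates the statistical structure the indices assume rather
than any real population: a mixture of archetypes, each with a weekly
visit probability (engaged ≈ 0.85–0.90, sporadic 0.35), a truncated-Poisson
number of visit days per active week (≈ 1.5–4), per-menu daily usage
probabilities, a multiplicative weekly decay of activity (0.96–0.998), and
a weekly discontinuation hazard
`base · exp(b_mi·s_mi + b_li·s_li + b_ri·s_ri)` driven by *archetype-level*
true engagement summaries (`s_mi` = mean menu probability,
`s_li = s_ri` = weekly visit probability — under weekly Bernoulli activity
the accessed-week fraction and the regularity of the visit series are
governed by the same parameter).  Driving dropout from true summaries
rather than computed indices avoids circularity: recovery tests check that
the computed indices *inherit* the association.  Defaults (233 patients,
540 days, base hazard 0.15/week, `b = (−0.3, −2.5, −0.3)`) live in
`src/engagekit/data/default_cohort.yaml` and give realistic dispersion:
roughly a third of patients never discontinue in-study, sporadic patients
mostly discontinue within six months.  Self-logging menus (meal, exercise,
weight, step count — the EI2 set) are habitual for engaged archetypes;
messaging and content-reading are occasional for everyone, so they add
noise to menu-level summaries by design.

Generation is week-level with uniform day placement inside the week, which
matches the indices' weekly resolution while exercising the day-based
45-day rule.  What the generator does **not** emulate: within-week
behavioural patterns (weekday/weekend structure), menu correlations beyond
the archetype level, re-engagement after discontinuation, demographic
covariate effects.  Passing tests therefore establish internal consistency
and recoverability under the assumed structure, not behavioural realism on
real app data.

Direct survival simulators (`simulate_cox_cohort`,
`simulate_two_group_survival`) generate exponential event times with known
log-hazard coefficients and administrative censoring for parameter-recovery
and log-rank calibration tests, independent of the event-log machinery.

## Numerical choices and problem sizes

- All cohort computations are pure functions of (log, window, combination,
  config): repeated runs are bit-identical; all simulation randomness flows
  through `numpy.random.Generator` seeds.
- PE pattern codes are base-`m` encodings of stable argsorts; entropy is
  accumulated in nats and clamped at 0 to avoid `-0.0`.
- Exhaustive PE validation covers all ternary sequences up to length 10
  for orders 2 and 3 (≈ 177k sequences) against a brute-force counter.
- Recovery simulations use the study-scale cohort size (n = 233): 200
  replicates for regression 3-SE coverage, 100 for Cox coefficient
  recovery, 1000/300 for log-rank size and power — sizes at which the
  checks are stable yet the whole suite runs in about a minute.

## Known limitations

- MI's clipping means the index is not a metric embedding; two patients
  can both score 1.
- The enriched LI and MI are cohort-relative: a patient's score changes if
  the cohort changes, so cross-study comparisons require a fixed reference
  cohort.
- With `T = 13` weekly observations, PE at order 3 has at most 11 windows
  for 6 possible patterns; the entropy estimate is coarse and RI values
  are correspondingly granular.
- The Cox model treats the 1-day times assigned to fully inactive patients
  as genuine early events; with many such patients the baseline hazard is
  distorted near t = 0.
- In-sample R² favours models whose components are autocorrelated across
  windows; it does not measure out-of-sample predictive skill.
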