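# Methods

This note documents the statistical model behind the synthetic cohort
generator, the conventions used by each analysis stage, and the design
choices made where more than one reading of the underlying rules was
possible.

## Data model

One *session* is one execution of the home protocol: a CAT symptom score
(0–40), one minute of pulse oximetry summarised as a single SpO₂ (%) and
heart-rate value, then at least three IC manoeuvres followed by at least
three forced-expiration manoeuvres from which FEV₁ is taken. Sessions occur
in an AM or a PM half of the day (cutoff 12:00 when the half is not
recorded); the protocol schedules both halves on three days per week, i.e.
six sessions per week. The canonical file format is a long CSV with one row
per effort; session-level fields repeat across the session's rows.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which every downstream stage is verified. The generative model for the true
(noise-free) session value of marker *m* in participant *i* is

    truth = baseline_i + drift(week) + diurnal_offset_m · 1[PM] + day_noise(day)

with

- **drift**: a weekly Gaussian random walk (SD `drift_sd`, default
  0.02 L/week), one walk per participant *shared by FEV₁ and IC* — slow
  physiological change moves both markers together;
- **day noise**: one draw per calendar day, shared by that day's AM and PM
  sessions so diurnal differences remain estimable; FEV₁ and IC day noises
  are correlated (`fev1_ic_day_corr`, default 0.8);
- **effort noise**: i.i.d. Gaussian per manoeuvre on top of the session
  truth. Within-day variation beyond the fixed diurnal offset therefore
  comes from effort noise alone; the within-day/between-day variance
  partition is an assumption, exposed entirely through the `CohortSpec`
  parameters.

Whole sessions are missed i.i.d. with probability `1 − adherence_prob`
(default adherence 0.906). Each manoeuvre is flagged invalid with probability
`p_invalid_effort` (default 0.02) and an invalid manoeuvre is repeated with
probability `p_retry` (default 0.7), at most two retries (≤ 5 efforts per
test type) — matching a protocol that allows but does not force repeats.

CAT is generated as `cat_baseline + ic_cat_coupling · z + N(0, cat_sd)`,
rounded and clipped to [0, 40], where `z` is the standardized deviation of
the session's true IC from baseline; a negative coupling (default −0.35)
yields the weak negative IC–CAT correlations seen in monitored cohorts. SpO₂
and heart rate are constant-plus-noise only.

### Default calibration

Defaults describe a stable monitored cohort of 11 participants over 26 weeks.
Noise SDs were calibrated *jointly* so the observable summaries land at
realistic magnitudes, because the session value is a nonlinear functional of
the efforts (largest of three for FEV₁, mean of three for IC):

| parameter | default | rationale |
|---|---|---|
| `effort_sd_fev1` | 0.05 L | top-two gap of 3 draws ≤ 150 mL ≈ 99 %, ≤ 100 mL ≈ 93 % |
| `effort_sd_ic` | 0.16 L | IC CV buckets ≈ 52/78/88 % at 5/8/10 % (IC is harder unsupervised) |
| `day_sd_fev1` | 0.064 L | with the max-of-3 effort noise, SD(ΔFEV₁) ≈ 105 mL → 2-SD range ≈ ±210 mL |
| `day_sd_ic` | 0.064 L | with the mean-of-3 effort noise, SD(ΔIC) ≈ 160 mL |
| `diurnal_offset_*` | +0.04 L | PM values slightly higher than AM |
| `fev1_ic_day_corr` | 0.8 | session-level r(FEV₁, IC) ≈ 0.45–0.5 after effort-noise dilution |

A Gaussian model cannot reproduce heavy-tailed effort failures, learning
effects, autocorrelated bad days, or informative missingness; passing tests
demonstrate that the *pipeline* recovers what the model encodes, not that
real cohorts behave this way.

Synthetic exacerbations multiply the truth by `1 − drop_frac · severity(day)`
with a trapezoidal severity (linear ramps of `ramp_days` at both ends) and
raise CAT by `cat_rise · severity`. They exist purely to probe detector
sensitivity; with a 30 % drop ramped over ~6 days every AM/PM stream contains
at least two consecutive > 50 mL falls by construction.

## Quality control

- *Best efforts*: the up-to-three largest operator/device-valid efforts,
  ties broken by manoeuvre order. The visual-inspection step of a human
  over-reader is represented by the `valid` input flag.
- *FEV₁ repeatability*: gap between the two largest selected efforts. Two
  conventions coexist — strict `< 0.150 L` as the acceptability criterion
  and `≤ 150 / ≤ 100 mL` as reporting buckets — and both are computed and
  emitted, since at 1 mL device resolution the distinction is immaterial in
  practice. Derived gaps and CVs are rounded at micro-litre resolution
  before comparison so exact boundary values (0.150 L, 5 %) are not
  misclassified by floating-point artifacts.
- *IC CV*: sample SD (n−1) over mean of the selected efforts. The SD flavour
  is not dictated by the guidelines; the choice is recorded in the report
  metadata. The session IC is the mean of **all** selected efforts, not only
  of those passing a CV screen — an open interpretive point, flagged here.
- *Session values*: largest valid FEV₁; mean of selected IC efforts.
- *Report denominators*: completeness fractions are over all sessions;
  repeatability/CV fractions over sessions with ≥ 2 valid efforts of the
  marker. Every output row carries its denominator and convention.

## Adherence

Adherence = executed / scheduled sessions over the eligible span: from the
participant's first session plus a 14-day learning phase (anchored per
participant, since enrolment dates differ) to the study end, minus
agreed exclusion windows. Scheduled counts are pro-rated at
`scheduled_per_week × days/7`, rounded to the nearest integer for partial
weeks; whether real studies pro-rate partial weeks is typically unstated, so
the convention is explicit here. Ratios above 1 (over-measuring) are
reported as-is with a `capped` flag. The cohort figure is pooled
(total executed / total scheduled); the per-participant mean is also
emitted.

## Variability

- *Deltas*: differences between consecutive recorded sessions of a stream
  (ALL, AM, PM). Missing values are skipped so nearest recorded neighbours
  are paired; calendar gap size is ignored by default (home cohorts measure
  every 2–3 days), with an optional `max_gap_days` cutoff for long breaks.
- *2-SD range*: mean ± 2·sample SD of deltas — not percentiles, because a
  nonzero mean delta should shift the envelope asymmetrically. Pooled raw
  deltas by default; averaging per-participant SDs is available
  (`pooled=False`) since the two differ under heterogeneous variances.
- *Relative density*: Gaussian KDE with Silverman's rule per participant,
  normalized on a shared grid, then averaged so each participant weighs
  equally (normalize-then-average). Each curve integrates to 1 ± 10⁻³; an
  all-identical delta series yields a flagged point-mass spike instead of a
  KDE.
- *Weekly means*: consecutive 7-day blocks from the first post-learning
  session; empty weeks are emitted with `n_sessions = 0`.
- *Monthly home/baseline ratios*: 28-day blocks post-learning; "first" is
  block 1 and "last" the final complete block, AM and PM separately, each
  divided by the supervised baseline value.

## Decrease periods

Within one stream, a qualifying step is a fall of > 50 mL (`per_step` mode)
or any fall (`total` mode, with the cumulative fall required to exceed
`total_threshold`). A period is a maximal run of ≥ 2 qualifying steps; the
next value classifies termination: rise > 50 mL → *rebound*; otherwise →
*unchanged*; series end → *censored*. Scanning resumes at the terminating
value. Design choices:

- Both modes exist because the per-step and total readings of "significant
  successive decrease" are genuinely different rules: two > 50 mL steps
  *always* total > 100 mL, so counts of runs whose total merely exceeds
  50 mL or 100 mL can only be produced by the total-mode reading. The
  per-step rule is the default; the mode is a config key.
- A small fall (≤ 50 mL) after a period counts as "unchanged" — the
  tripartite rebound/unchanged/censored accounting leaves no other class.
- The onset-above-mean flag compares the period's first value with the
  participant's overall post-learning mean of the *same stream*, consistent
  with stream-restricted deltas.
- Periods do not extend through unchanged steps by default (the stricter
  reading); `extend_through_unchanged=True` absorbs within-threshold plateau
  steps, counting only qualifying falls in `n_steps`.
- An "n-day period" label counts decrease steps, not calendar days.

The scanner is verified against a brute-force enumeration of all maximal
qualifying windows on random series, and on stationary symmetric-noise
cohorts the counts of decrease periods and mirror-image increase periods
agree within sampling error.

## Association

Pearson correlations per participant over pairwise-complete session-level
pairs (AM and PM both included; session-level rather than daily averages,
because the markers are recorded per occasion). Cells need ≥ 3 pairs and
nonzero variance. Cross-participant summaries report the median and the IQR
width (Q3 − Q1, linear interpolation — recorded in the output since printed
IQRs from rounded inputs are convention-sensitive), plus the count of
participants at or above a strength threshold (default r ≥ 0.40,
"moderate"). Group contrasts are descriptive: paired same-day PM − AM
differences and beginning/mid/late tertile means of each participant's
post-learning span. Mixed-effects modelling of these contrasts is a routine
fit for off-the-shelf tools and is intentionally out of scope.

## Numerical and degenerate-input conventions

- All randomness flows from a single `numpy` Generator seeded by
  `CohortSpec.seed`; draws are consumed in a fixed order (and consumed even
  for skipped sessions) so outputs are byte-identical given a seed and
  missingness does not perturb later values.
- Fewer than 2 efforts → repeatability/CV missing with reason; < 3 values →
  no decrease periods; < 2 deltas → no 2-SD range; < 5 deltas → no density
  curve; empty eligible span → adherence undefined with reason
  `"no eligible span"`.
- Volumes are written at 0.1 mL precision in the session CSV; participant
  baselines at full double precision.

## Problem sizes

Tests and the acceptance script run simulated cohorts at the study scale —
11 participants × 26 weeks × 6 scheduled sessions/week (~1700 scheduled
sessions) — and use larger cohorts (e.g. 64 participants, or two-year spans)
only where a recovery criterion needs the extra sampling precision. The
whole suite completes in well under a minute.

## Known limitations

- The generator's Gaussian, i.i.d.-by-day world underestimates outliers,
  learning effects and autocorrelation of real home spirometry.
- Adherence missingness is non-informative by construction; real skips
  cluster around bad days.
- No flow-curve level QC (back-extrapolation, end-of-test criteria): effort
  validity is an input flag.
- The IC "average" convention (all selected efforts vs CV-passing efforts)
  and the pooling convention of 2-SD ranges are interpretive choices,
  exposed as options and recorded in output metadata.
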