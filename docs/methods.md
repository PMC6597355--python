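# Methods

## Scope and structure

`ptsdce` implements a cost-utility analysis of early cognitive therapy for
child/adolescent PTSD against waitlist usual care, in five stages: a
synthetic trial-cohort generator (`synthetic_cohort`), SDQ→CHU-9D utility
mapping and QALY accrual (`utility_qaly`), resource-use and intervention
costing (`costing`), trial-horizon incremental analysis (`trial_cua`), a
two-state Markov extrapolation (`markov`) and probabilistic/one-way
sensitivity analysis (`uncertainty`).  The clinical content of the therapy,
the service-use instrument itself, and re-estimation of the SDQ→CHU-9D
crosswalk are out of scope; the crosswalk coefficients are taken as given.

## Utility mapping and QALYs

The crosswalk is linear in the five SDQ subscales with coefficients
(0.88, −0.019, −0.009, −0.001, −0.008, +0.005).  Its analytic range over the
valid domain is [0.51, 0.93]; values are therefore never clamped, and
out-of-domain scores raise an error naming the subscale rather than being
clipped.  QALYs over the trial window use the trapezoid between baseline and
follow-up utilities with duration 11/52.18 years.  No discounting applies
inside the trial window (horizon < 1 year).

## The synthetic cohort

The generator emulates the study conditions the analysis assumes, not real
children:

- Arms of 14 (treatment) and 15 (control); every child has PTSD at entry.
- Follow-up recovery is Bernoulli per arm, defaults 0.71 / 0.27.
- SDQ subscales are drawn as rounded, clipped (0–10) normals (SD 1) around
  state-specific profiles; the emotional-problems mean is back-solved so the
  mapped utility mean lands at the target: 0.734 in the PTSD state and 0.91
  when recovered.  The recovered target cannot reach the often-quoted ≈0.93
  because that is the exact maximum of the mapping, unattainable as a mean
  of a non-degenerate bounded distribution; rounding/clipping also biases
  the realised means by ~0.01, which the tests' tolerances absorb.
- Resource-use counts per category are zero-inflated rounded Gamma draws
  (floored at 1 when non-zero), giving the zero-heavy right-skewed cost
  pattern typical of child mental-health service use; recovered children
  draw from a higher zero-inflation at follow-up.
- Therapy contact minutes (treatment arm only) come from a Beta scaled to
  [195, 755] with mean 636.25.
- Missingness is missing-completely-at-random per record at 20%, masking
  the entire follow-up block and never baseline — the simplest mechanism
  consistent with missingness not differing between arms.
- Ages 8–17 uniform and Bernoulli(½) gender exist only to exercise the
  covariate-adjustment stage.  Costs and outcomes are independent given
  recovery status by default (`cost_outcome_correlation` reserves the knob,
  as no within-arm correlation structure is documented anywhere).

Passing tests on this cohort demonstrate that the pipeline's estimators
recover known inputs under MCAR missingness and conditional independence;
they do not validate behaviour under informative missingness, clustered
service use, or real SDQ trajectories.

## Costing

Unit costs are a CSV-style table (category, service class, unit, GBP,
index-trauma flag) at 2014 prices.  The packaged default table is
illustrative — the source evaluation prints only aggregate cost means, not
per-category unit costs — so per-category totals are not canonical;
structure (hospital vs community, index-trauma exclusion) is.  The
intervention is costed as contact minutes / 60 × £138.  All arithmetic is
unrounded; whole-GBP rounding (half away from zero) is applied only at
reporting, so 636.25 min → £1463.375 → £1463.

## Trial-horizon analysis

"Conditional regression" imputation is a single deterministic OLS
prediction of each missing follow-up cost/utility from arm, the
corresponding baseline value, age and gender; optional seeded residual
noise is available but off by default — with n = 29 multiple imputation
would be over-engineered.  Covariate adjustment uses an identity-link
linear model, so the group coefficient is directly a difference in GBP or
QALYs; a log-link Gamma GLM is available for skew-robustness checks, with
the caveat that its group coefficient is a log ratio.  ICERs are reported
rounded to the pound; comparisons always use unrounded values.  When
ΔE = 0 the ICER is undefined and the result signals that net monetary
benefit (λ·ΔE − ΔC) should be reported instead.

## Markov model conventions

Two states (PTSD, PTSD-free absorbing — relapse after a single acute trauma
is taken as negligible), 3-month cycles, 12-cycle horizon.  Numerical
conventions, each of which was genuinely open and is fixed as follows:

- **Transition timing**: recovery multiplies the PTSD occupancy by
  (1 − 0.129) at the *start* of each of cycles 2–4, before accrual.  This
  convention, with the per-cycle state values, reproduces the published
  year-1 totals to within 0.15%; end-of-cycle transitions do not.
- **State values**: the per-cycle values (£549/£236, 0.185/0.193) are
  canonical.  The published *annual* state values are mutually inconsistent
  with them (£549 × 4 = £2,196 ≠ £2,596) and are not used.
- **Trial cycle**: cycle 1 accrues the arms' imputed trial totals
  (£1,686/0.1979 vs £307/0.1823) even though 11 weeks ≠ 13; the 3-month
  cycle is explicitly an approximation of the trial period.
- **Natural recovery** applies to the residual PTSD fraction of *both*
  arms, and only in year 1 (no evidence of later spontaneous recovery);
  over three cycles it remits 1 − 0.871³ ≈ 33.9% of the PTSD mass,
  consistent with the 34% nine-month source estimate.
- **Discounting**: none in year 1; cycles in year y ≥ 2 carry
  (1.035)^−(y−1) (per year block).  A smooth per-cycle alternative is
  provided but off by default.
- **No half-cycle correction** by default (year-1 reproduction succeeds
  without it); an option averages pre- and post-transition occupancy.

The published cumulative totals for years 2–3, the 3-year ICER (printed
both as £2,205 and £2,250) and the training-cost ICER (£16,187) could not
be reconciled with any combination of the above conventions and are treated
as non-canonical; the engine's correctness at those horizons is instead
guaranteed by structural properties (occupancy conservation to 1e−12,
absorbing-state monotonicity, exact zero-rate discounting identity, and
agreement with an independent 10⁵-individual microsimulation within
Monte-Carlo error).

## Probabilistic sensitivity analysis

Distributions: efficacies Beta(19, 7) and Beta(3, 9); state costs
Gamma(19.532, 28.118) and Gamma(10.369, 22.738), whose means reproduce
£549/£236; state QALYs Beta(808, 3567) and Beta(2618, 10940).  The source
table pairs the two QALY Betas against the wrong stated means (Beta(2618,
10940) has mean 0.193, printed against 0.185, and vice versa); each Beta is
assigned to the state whose stated mean it matches, and a warning is
emitted.  The 9-month remission probability is sampled from a Beta
moment-matched to mean 34% with 95% CI 21%–49% — Beta(14.614, 28.368) — and
converted to the 3-month cycle probability per draw; the alternatively
printed Beta(14, 95), whose mean 0.128 already sits on the 3-month scale,
is available via `remission_scale="three_month"`.  All parameters are
sampled independently (no correlation structure is documented); trial-cycle
costs and QALYs are held fixed, having no assigned distributions.  The
default is 5,000 draws; the draw loop is vectorised across draws, so the
full PSA runs in well under a second.  CEAC thresholds run £0–£50,000 in
£500 steps, covering the £20,000–£30,000 decision anchors.

One-way scenarios: *training costs* adds the straight-line amortized £186
per treated patient (a one-off training outlay spread over 5 years × 29
patients/year) to the treatment arm's cycle-1 cost; *complete case* swaps
in the complete-case initial distributions (90%/18%), PTSD-free state
values (£264.55, 0.2027) and — for internal coherence — the complete-case
trial-cycle totals (£1,691/0.1929, £351/0.1851).

## Degenerate inputs and tolerances

Probability conversion rejects p = 1 (infinite rate) and non-positive
durations; its round-trip is exact to 1e−12 for duration ratios within
[¼, 4] and p ≤ 0.95 (beyond that the short-horizon probability saturates to
1.0 in floating point).  Occupancies are checked against [0, 1] at every
cycle with 1e−12 slack.  Zero-variance (degenerate) PSA distributions
collapse exactly to the deterministic model, which doubles as the
cross-check between the scalar cohort engine and the vectorised PSA engine.

## Problem sizes

Monte-Carlo checks in the test suite use 20,000 children per arm for
generator-calibration properties (Monte-Carlo error ≈ 0.003 on a
proportion), 10⁵ individuals for the microsimulation oracle, and 5,000 PSA
draws — the analysis' own default — for quadrant and CEAC checks.
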