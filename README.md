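# ptsdce

Cost-utility analysis of early cognitive therapy for post-traumatic stress
disorder (PTSD) in children and adolescents, as a tested, reusable Python
pipeline: synthetic trial cohort → SDQ→CHU-9D utility mapping and QALY
accrual → NHS-perspective costing → trial-horizon incremental analysis →
two-state Markov extrapolation to three years → probabilistic and one-way
sensitivity analysis.

It is written for health economists and methods researchers who want to
reproduce, stress-test or extend a trial-based economic evaluation of an
early psychological intervention, without access to the (small,
confidential) patient-level trial data: a seeded generator emulates the
trial's statistical structure, and every downstream stage is exercised
against it.

## The model

**Utilities.** Parent-completed Strengths and Difficulties Questionnaire
(SDQ) subscale scores map to a Child Health Utility 9D (CHU-9D) weight via a
published linear crosswalk,

    u = 0.88 − 0.019·emotion − 0.009·conduct − 0.001·hyper − 0.008·peer + 0.005·prosocial,

which spans [0.51, 0.93] over the valid SDQ domain.  QALYs are the
trapezoidal area under the utility line over the 11-week trial window.

**Trial analysis.** Costs price resource-use counts with 2014 unit costs
plus therapy contact time at £138/hour; missing follow-up data are imputed
by conditional regression; between-arm differences are adjusted for baseline
cost/utility, age and gender; and the incremental cost-effectiveness ratio
is ICER = ΔC/ΔE with dominance classification on the cost-effectiveness
plane.

**Extrapolation.** A two-state cohort Markov model (PTSD / PTSD-free,
absorbing) runs in 3-month cycles over 3 years.  Each arm enters split by
its end-of-trial recovery proportion (71% vs 27% PTSD-free); cycle 1 accrues
the observed trial totals; natural recovery continues in cycles 2–4 at the
per-cycle probability p₃ = 1 − exp(ln(1 − 0.34)·3/9) = 0.129; cycles accrue
state costs (£549 / £236) and QALYs (0.185 / 0.193) weighted by occupancy,
discounted at 3.5%/year after year 1.

**Uncertainty.** The probabilistic sensitivity analysis samples efficacies
and state QALYs from Beta distributions, state costs from Gammas and the
9-month remission probability from a Beta (converted per cycle), re-running
both cohorts for every draw; cost-effectiveness acceptability curves report
P(λ·ΔE − ΔC > 0) over willingness-to-pay thresholds λ.

## Worked example

```sh
python examples/03_markov_extrapolation.py
```

prints (abridged):

```
3-month recovery probability from 9-month 0.34: 0.129

treatment arm (enters 71% PTSD-free):
  year 1: cumulative cost £2601.90, QALYs 0.772
control arm (enters 27% PTSD-free):
  year 1: cumulative cost £1538.34, QALYs 0.748

incremental analysis (treatment vs usual care):
  year 1: ΔC £1063.56, ΔE 0.0237, ICER £44,948/QALY
  year 3: ΔC £ 372.06, ΔE 0.0413, ICER £9,001/QALY
```

Year 1 reproduces the published model totals (£2,598 / £1,540 and QALYs
0.773 / 0.748) to within rounding.  The upfront therapy cost (~£1,463 for a
mean 636.25 contact minutes) is progressively offset as the larger recovered
share of the treated cohort uses fewer services and lives at higher utility,
so the ICER falls steeply with horizon.  `examples/04_psa_ceac.py` adds the
probabilistic analysis: with 5,000 draws about 68% fall in the north-east
quadrant (more costly, more effective) at 3 years, and the probability of
cost-effectiveness at £20,000–£30,000 per QALY is printed from the CEAC.
The other examples cover cohort generation and the trial-horizon analysis.

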