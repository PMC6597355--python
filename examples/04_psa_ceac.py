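"""Probabilistic and one-way sensitivity analysis.

Draws 5,000 parameter vectors (Beta efficacies and state QALYs, Gamma state
costs, Beta 9-month remission converted per cycle), re-runs both arms' 3-year
cohorts per draw, and summarises the joint uncertainty as quadrant shares on
the cost-effectiveness plane and a cost-effectiveness acceptability curve.
Then repeats the model under the training-cost and complete-case scenarios.
"""

from ptsdce import ceac, run_variant, sample_psa

draws = sample_psa(5000, seed=1)
shares = draws["quadrant"].value_counts(normalize=True)
print("3-year cost-effectiveness plane quadrant shares (5,000 draws):")
for quadrant in ("NE", "SE", "NW", "SW"):
    print(f"  {quadrant}: {shares.get(quadrant, 0.0):5.1%}")
print("(NE = treatment costs more and gains more; SE = cheaper and better)")

curve = ceac(draws)
for threshold in (20000.0, 30000.0):
    p = curve.loc[curve.threshold == threshold, "probability"].iloc[0]
    print(f"P(cost-effective at £{threshold:,.0f}/QALY) = {p:.2f}")

for variant in ("training_costs", "complete_case"):
    res = run_variant(variant, n_draws=5000, seed=1)
    det = res.deterministic[3]
    p20 = res.ceac.loc[res.ceac.threshold == 20000.0, "probability"].iloc[0]
    p30 = res.ceac.loc[res.ceac.threshold == 30000.0, "probability"].iloc[0]
    print(f"\n{variant}: 3-year ΔC £{det.adjusted_cost_diff:,.0f}, "
          f"ΔE {det.adjusted_qaly_diff:.4f}, "
          f"P(CE at £20k-£30k) = {p20:.2f}-{p30:.2f}")
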