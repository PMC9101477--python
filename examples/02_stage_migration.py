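"""Quantify nodal stage migration as a function of the ELN count.

Fits the continuous-ELN logistic model (OR per additional examined node,
adjusted for T stage) and the per-count OR curve against the one-ELN
reference — the curve the cutpoint analysis consumes.
"""

from elncut import default_config, fit_continuous_or, generate_cohort, per_count_or_curve

cohort = generate_cohort(default_config(n_patients=50_000, seed=5, mode="piecewise"))

fit = fit_continuous_or(cohort)  # adjusted for T stage
lo, hi = fit.ci95
print(f"OR per ELN: {fit.or_per_eln:.3f} (95% CI {lo:.3f}-{hi:.3f}), P = {fit.p_value:.2e}")

curve = per_count_or_curve(cohort, reference_count=1)
print("\nper-count OR vs 1 ELN (first 20 levels):")
print(curve.to_frame().head(20).to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# An OR above 1 per ELN means each extra examined node raises the odds of
# being classified node-positive: with few nodes examined, positive nodes
# are missed. The per-count curve rises steeply and then flattens — the
# flattening point is the candidate minimum adequate lymphadenectomy.
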