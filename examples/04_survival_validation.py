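"""Validate a 16-ELN cutoff against overall survival.

Three views, each within observed nodal strata: the continuous Cox HR per
ELN, the Kaplan-Meier comparison at the cutoff, and the beyond-cutoff HR
curve that asks whether dissecting more than the cutoff keeps helping.
"""

from elncut import (
    default_config,
    fit_cox_continuous,
    generate_cohort,
    km_compare_at_cutoff,
    per_count_hr_curve,
)

cohort = generate_cohort(default_config(n_patients=50_000, seed=5))  # mechanistic mode
CUTOFF = 16

for stratum in ("node-negative", "node-positive"):
    fit = fit_cox_continuous(cohort, stratum=stratum)
    lo, hi = fit.ci95
    print(f"{stratum}: HR per ELN {fit.hr_per_eln:.3f} (95% CI {lo:.3f}-{hi:.3f})")

above, below, lr = km_compare_at_cutoff(cohort, CUTOFF, stratum="node-negative")
print(f"\nnode-negative at the {CUTOFF}-ELN split:")
for s in (above, below):
    med = "not reached" if s.median_months is None or s.median_months == float("inf") \
        else f"{s.median_months:.1f} mo"
    print(f"  {s.label}: n={s.n}, median OS {med}, 5-year OS {100*s.survival_at_60mo:.1f}%")
print(f"  log-rank chi2 = {lr.chi_square:.1f}, p = {lr.p_value:.2e}")

curve = per_count_hr_curve(cohort, stratum="node-negative", reference_count=CUTOFF)
print("\nbeyond-cutoff HR vs 16 ELNs (node-negative), first levels:")
print(curve.to_frame().head(8).to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# Under-staging drives the survival gap: patients with few examined nodes
# include hidden node-positives, so the <cutoff "node-negative" group dies
# faster. Beyond the cutoff the HR curve is flat — more dissection no longer
# changes survival once staging is adequate.
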