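# elncut

How many lymph nodes must be examined at esophagectomy after neoadjuvant
chemoradiotherapy (nCRT) for the nodal stage to be trustworthy? Too few
examined lymph nodes (ELNs) leave positive nodes undetected, so patients are
under-staged ("stage migration": the apparent N0→N+ shift as sampling
deepens), and the under-staged patients drag down the survival of the
observed node-negative group. `elncut` implements the registry-analysis
pipeline that locates the **minimum adequate lymphadenectomy**:

1. **Stage migration** — logistic models of observed nodal positivity vs the
   ELN count *n*, adjusted for T stage: the continuous OR per extra node and
   the per-count OR curve against a one-ELN reference.
2. **Cutpoint detection** — the log-OR curve is smoothed with Cleveland's
   LOWESS (bandwidth 2/3) and a **Chow-test scan** fits pooled vs two-segment
   regressions at every candidate count *k*:

   F(k) = [(RSS_p − RSS_1 − RSS_2)/2] / [(RSS_1 + RSS_2)/(n_1 + n_2 − 4)]

   The arg-max of F is the structural break n̂\* — the ELN count beyond which
   additional sampling stops re-classifying patients.
3. **Survival validation** — Cox PH fits of overall survival on *n* within
   observed nodal strata (Efron ties), Kaplan–Meier comparison at the cutoff
   with log-rank tests, and beyond-cutoff HR curves testing whether
   dissection past n̂\* still improves survival.
4. **Synthetic cohorts** — registry microdata cannot be redistributed, so a
   seeded generator reproduces the statistical structure the analysis
   assumes: ELN counts drifting upward by diagnosis era (median 9→15,
   overall 12, IQR 7–19), latent nodal disease observed through node
   sampling (piecewise-logit mode with a plantable breakpoint n\*, or a
   mechanistic hypergeometric nodal-basin mode), and exponential
   proportional-hazards survival with right censoring. The planted n\* makes
   the whole pipeline testable by parameter recovery.

Intended users: biostatisticians and surgical-oncology researchers who want
a tested, reusable implementation of the OR-curve / Chow-break cutpoint
procedure, or a simulation bench for studying its operating characteristics.

## Worked example

```python
from elncut import default_config, generate_cohort, find_cutpoint

cohort = generate_cohort(default_config(n_patients=50_000, seed=5, mode="piecewise"))
bp = find_cutpoint(cohort, curve_source="migration")
print(bp.k_hat, bp.significant)
```

Running `python examples/03_find_cutoff.py` prints:

```
estimated cutoff: 16 ELNs (true planted value: 16)
Chow F at cutoff: 129.1; pointwise p = 1.67e-21; scan-adjusted p = 9.01e-20; significant: True
```

The cohort was generated with a true stage-migration breakpoint at 16 ELNs;
the scan recovers it exactly, and the scan-adjusted p-value (Bonferroni over
all candidate breaks) confirms the break is real. Validating against
survival (`python examples/04_survival_validation.py`):

```
node-negative: HR per ELN 0.989 (95% CI 0.987-0.990)
node-negative at the 16-ELN split:
  ELN>=16: n=10532, median OS 58.2 mo, 5-year OS 48.7%
  ELN<16: n=24310, median OS 45.5 mo, 5-year OS 41.2%
  log-rank chi2 = 145.2, p = 1.96e-33
```

Each examined node lowers the observed node-negative group's hazard (HR
0.989 < 1): thorough sampling purges hidden node-positives from the N0
label, and the ≥16-ELN "node-negative" patients accordingly live longer
(median 58.2 vs 45.5 months). Beyond the cutoff the per-count HR curve is
flat — once staging is adequate, more dissection no longer changes survival.

The other scripts in `examples/` cover cohort simulation and descriptives
(01), the migration models (02), and the full report bundle (05). The same
stages are available as a CLI:

```bash
elncut simulate --seed 2 --n 20000 --out cohort.csv
elncut cutpoint cohort.csv --out breakpoint.json
elncut report cohort.csv --out-dir results/
```

## Documentation

The model, generator assumptions, numerical choices and known limitations
are documented in [`docs/methods.md`](docs/methods.md).
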