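# vancopta

Population pharmacokinetic/pharmacodynamic simulation and dose-finding for
**vancomycin in adults with chemotherapy-associated febrile neutropenia**.

Vancomycin dosing in this population is usually guided either by the trough
concentration (Cmin 15–20 mg/L) or, per current guidelines, by the exposure
ratio AUC24/MIC ≥ 400. The two indices do not behave alike: the AUC-based
targets respond to the daily dose and renal function, while the trough-based
target is driven by how the dose is scheduled. `vancopta` implements a
published two-compartment population model for this population and the
simulation machinery needed to quantify that difference and derive dose
recommendations.

## The model

Structural model: two-compartment kinetics with zero-order (infusion) input
and first-order elimination. Clearance depends on the estimated glomerular
filtration rate through a power model centred on the cohort median:

```
CL_pop(eGFR) = θ0 · (eGFR / 144)^θ1          θ0 = 5.2 L/h, θ1 = 0.62
```

with Q = 4.99 L/h, V1 = 21.22 L, V2 = 28.28 L. Between-subject variability
is lognormal, βᵢ = θ·exp(ηᵢ), with ω_CL = ω_V1 = 0.223, ω_Q = 0.767 and a
correlation ρ(η_V1, η_CL) = 0.62; V2 carries no random effect. The residual
error model multiplies the log prediction, ln y = ln f · (1 + b·ε) with
b = 0.025 (a conventional proportional model is available as a switch).

On top of the simulator the package provides

* **exposure & PTA** — log-trapezoidal AUC over the 72–96 h steady-state
  window, steady-state troughs/peaks, Monte-Carlo probability of target
  attainment (PTA) over regimen grids, and eGFR dose breakpoints;
* **surrogates** — small ReLU/sigmoid networks (Adam, MAE loss) that map
  (daily dose, interval, infusion time, eGFR[, log2 MIC]) directly to PTA,
  with exact Kernel SHAP variable attribution;
* **estimation** — a stochastic-EM (SAEM-style) fitter for the population
  model with empirical-Bayes estimates, bootstrap CIs and GOF metrics;
* **diagnostics** — prediction-corrected visual predictive checks;
* **synthetic data** — a generator that emulates the original study design
  (14 subjects, 1 g q12h in 2 h infusions, 7 samples per subject around the
  dose nearest 48 h) so every stage is testable without clinical data.

## Worked example

```python
from vancopta import DosingRegimen, TargetSpec, estimate_pta, egfr_breakpoint

regimen = DosingRegimen.from_daily_dose(2000, interdose_interval_ii=12,
                                        infusion_time_tinf=2)
res = estimate_pta(regimen, egfr=80.4, target=TargetSpec.auc_mic(mic=1.0),
                   n_subjects=1000, rng_seed=1)
print(f"PTA = {res.pta:.3f}  95% CI {res.ci95[0]:.3f}-{res.ci95[1]:.3f}")

bp = egfr_breakpoint(2500, TargetSpec.auc_mic(1.0), rng_seed=1)
print(f"2.5 g/day keeps PTA >= 0.90 up to eGFR {bp:.1f}")
```

prints

```
PTA = 0.919  95% CI 0.900-0.935
2.5 g/day keeps PTA >= 0.90 up to eGFR 121.0
```

i.e. the conventional 1 g q12h regimen attains AUC24/MIC ≥ 400 in ~92% of
simulated patients with eGFR 80.4 mL/min/1.73 m² (adequate, PTA ≥ 0.90),
and raising the daily dose to 2.5 g extends adequacy to an eGFR of about
121 mL/min/1.73 m². The same engine is available from the shell:

```bash
vancopta pta --dd 2000 --egfr 80.4 --mic 1 --seed 1 --out run/
vancopta surface --target cmin-range --tinf 12 --seed 1 --out run/
vancopta gen-data --seed 7 --out run/ && vancopta fit --dataset run/dataset.csv --out run/
```

Every command writes a `manifest.json` (config hash, seed, version) so runs
are reproducible bit for bit.

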