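# Methods

## Model

Vancomycin disposition is described by a linear two-compartment model with
zero-order infusion input and first-order elimination from the central
compartment. The micro-constants are k10 = CL/V1, k12 = Q/V1, k21 = Q/V2;
the central concentration is evaluated with the closed-form biexponential
solution (hybrid rates α, β) superposed over all administered doses. The
closed form is the production evaluator because PTA work needs millions of
profile evaluations; an adaptive-step ODE integration of the mass-balance
system exists only as an independent oracle in the test suite, where the
two are required to agree to 1e-6 relative. If α and β ever coincide to
within 1e-9 relative (possible only for contrived parameter sets), k21 is
perturbed by 1e-7 relative rather than switching to the confluent limit
form; the induced error is far below residual noise.

Clearance carries the single covariate of the final model, a power law on
the estimated glomerular filtration rate centred on the cohort median of
144 mL/min/1.73 m²: CL_pop = θ0 · (eGFR/144)^θ1. Reference values:
θ0 = 5.2 L/h, θ1 = 0.62, Q = 4.99 L/h, V1 = 21.22 L, V2 = 28.28 L.

Between-subject variability is lognormal, βᵢ = θ·exp(ηᵢ), with
η = (η_CL, η_Q, η_V1) ~ MVN(0, Σ). The log-scale SDs are 0.223, 0.767 and
0.223; the only nonzero correlation is ρ(η_V1, η_CL) = 0.62. The reported
"ω² (%)" values are interpreted as SD(η)×100, the dominant convention for
lognormal BSV; this reading is corroborated by the eGFR breakpoint
computation, which reproduces the published 122.4 mL/min/1.73 m² value for
2.5 g/day almost exactly under ω_CL = 0.223. V2 has no random effect.

Two residual-error models are implemented. The default applies the noise
multiplicatively on the log prediction,

    ln y = ln f · (1 + b·ε),   ε ~ N(0,1),   b = 0.025,

so SD(ln y | f) = b·|ln f| grows with ln f. This is the literal reading of
the published equation; because it differs from the conventional Monolix
proportional models, a standard proportional alternative
(y = f·(1 + b·ε)) is available via `ResidualErrorSpec(mode=...)`. Which of
the two the original software actually fitted cannot be determined from
the text, so both are first-class and tested.

## Exposure and target attainment

Steady state is realized by explicit simulation from t = 0 with doses
through 96 h (not by the analytic steady-state formula), and exposure is
measured over the 72–96 h window. The AUC uses the log-trapezoidal rule —
per segment (c1−c2)Δt/ln(c1/c2) when both endpoints are positive and
unequal, linear trapezoid otherwise — on a 0.25 h grid with every infusion
start/stop forced onto the grid so the peak at infusion end is never
missed. AUC24 is the window AUC rescaled to 24 h (an identity for the
default window). Cmin,ss is the minimum over the window, which equals the
pre-dose trough for intermittent regimens and remains well defined for
continuous (Tinf = II) infusion.

Three PK/PD targets are supported: AUC24/MIC ≥ 400 (primary efficacy
index), AUC24 in [400, 600] mg·h/L, and Cmin,ss in [15, 20] mg/L (both
upper-bounded to limit nephrotoxicity risk). PTA for a regimen is the
fraction of simulated subjects meeting the target; only between-subject
variability is simulated (residual error is measurement noise, not drug
exposure, and is applied only when generating observation datasets). MIC
is fixed per evaluation; no MIC distribution is modelled. Exact binomial
(Clopper–Pearson) 95% intervals accompany every PTA estimate.

Surfaces over daily-dose × eGFR grids and the eGFR breakpoint search use
**common random numbers** — one shared set of η draws across all grid
points — which makes surfaces smooth, makes monotonicity testable, and
makes the breakpoint bisection well posed (PTA is then a monotone step
function of eGFR; bisection runs to 0.5 eGFR units). Whether the original
analysis sampled eGFR per subject or fixed it per surface point is
unstated; it is fixed per point here (it is the axis variable).

Default problem sizes (1000 subjects per PTA point, 7×7 dose/eGFR grids)
reproduce the published dose recommendations in seconds per surface with
the closed-form evaluator.

## Surrogate networks

The simulator is reduced to two multilayer perceptrons: model 1 maps
(DD, II, Tinf, eGFR, log2 MIC) to PTA of AUC24/MIC ≥ 400; model 2 maps
(DD, II, Tinf, eGFR) to the two bounded-target PTAs jointly. Training data
are PTA labels on regimens drawn from DD ~ U(1000, 4000) mg/day,
eGFR ~ U(80, 150), II ~ U(2, 24) h, Tinf ~ U(1.5, II) h,
log2 MIC ~ U(−2, 2); the full protocol uses 3000 regimens × 1000 subjects
with a 2400/600 train/test split. Four architectures are compared (hidden
layers A = [5], B = [10], C = [10, 10], D = [10, 10, 10]; ReLU hidden
units, sigmoid output so predictions stay in (0, 1)) and the one with the
best test MAE is kept; the winner is recorded in the model artifact since
it is not fixed a priori. Training is Adam on MAE loss, batch 256, at most
1000 epochs, early stop after 30 epochs without improvement beyond 1e-10
on the training loss (no separate validation split). Inputs are
standardized with the mean/SD of the complete dataset before splitting;
this leaks test-set moments by construction and is retained deliberately
as part of the stated protocol rather than corrected.

The test suite and CLI default to a desk scale of 500 regimens × 300
subjects, which trains in seconds; expected MAEs are correspondingly wider
than at the full scale because the labels themselves carry Monte-Carlo
noise of SD ≈ √(p(1−p)/n_subjects).

## Kernel SHAP

With at most five inputs, all 2^M coalitions are enumerated and the
Shapley-kernel-weighted least-squares problem is solved exactly (the empty
and full coalitions enter as hard constraints), so attributions equal the
exact Shapley values of the coalition value function and carry no solver
stochasticity. Missing features are imputed by averaging the model output
over a 400-row background sample from the training data. This
marginalization assumes feature independence; the training distribution
violates it through Tinf ≤ II, so coalitions that mix II from one regimen
with Tinf from another can land on physically impossible inputs where the
surrogate extrapolates. This is a known caveat of the method, inherited
here deliberately. Explanations are computed for a fresh seeded sample
from the training distribution (respecting Tinf ≤ II).

A consequence worth stating: for the Cmin 15–20 mg/L index this
implementation ranks daily dose slightly above the interdose interval in
mean |SHAP| (with II and Tinf both above eGFR, and II + Tinf jointly
comparable to DD). Surrogate-free permutation importance on the simulator
labels gives the same ordering, so it is a property of the simulator under
this training distribution, not of the network or the attribution method.

## Estimation

The population fit is a stochastic EM in the SAEM family: a vectorized
random-walk Metropolis E-step samples η per subject (proposal covariance
from the current Ω, per-subject scale adapted toward 30% acceptance), and
the M-step updates fixed effects from the complete-data estimates —
(θ0, θ1) by regressing sampled log-CL on log(eGFR/144), Q and V1 from log
means, Ω from the residual second moment projected onto its structure
(free diagonal, single CL–V1 correlation), and b from the normalized
residuals of the observation model. V2, which has no random effect, is
updated by a bounded one-dimensional conditional-likelihood search inside
the M-step. Defaults are 600 burn-in iterations at step size 1 with
simulated annealing (variance terms may not shrink more than 5% per
iteration) and 300 smoothing iterations at step size 1/k; 6 Metropolis
transitions per iteration. These counts are this package's own defaults,
chosen so that a 50-subject study-design fit converges in a few seconds;
the exact settings of the original software are not published. With them,
the median recovered θ0 across 10 replicate 50-subject synthetic fits is
within ~2–4% of the generating 5.2 L/h.

Initial values are data-driven mass-balance guesses (CL from dosing rate
over mean concentration, V1 from dose over peak, Q = CL, V2 = V1, ω = 0.3,
b = 0.1); θ1 starts at 1 and is frozen automatically when the dataset has
no eGFR spread. Observations below the 3 µg/mL quantification limit are
excluded with a reported count (the original handling is undescribed). The
marginal −2 log-likelihood is computed at the end by importance sampling
(300 draws per subject around the conditional means); BIC adds
(number of population parameters)·ln(n_subjects), which suffices for the
relative model comparisons it is used for. A one-compartment variant
(η on CL and V1 only) supports structural-model comparison. Bootstrap CIs
resample subjects with replacement and refit; each refit's seed derives
from the resampled content, so duplicate resamples are cached and
identical data yield identical fits. RSE% from a Fisher information matrix
is not computed; bootstrap percentiles are the uncertainty summary.

## Diagnostics

The prediction-corrected VPC normalizes observed and simulated
concentrations by the typical (η = 0) prediction,
pcY = Y · median(PRED in bin)/PRED — the lower-bound-free variant of the
standard correction. Binning uses 7 equal-count bins on time after dose;
the design is re-simulated 1000 times (with BSV and residual error) and
per-bin percentiles of the observations are compared with 95% bands of the
same percentiles across replicates. The default percentiles 10/50/90 bound
an 80% empirical interval; 2.5/50/97.5 are available because the source
material is internally inconsistent about which was used. Calibration is a
statement in expectation over datasets: all bins of one dataset share the
same cohort of random effects, so a single unlucky cohort can push every
bin outside its band simultaneously — the tests therefore average coverage
over replicate datasets.

## Synthetic data

The generator emulates the study design: n subjects (default 14) on 1 g
q12h in 2 h infusions, 7 samples per subject at 1, 2, 4, 6, 8, 10 h after
the start of the infusion nearest 48 h plus a trough 30 min before the
next dose. eGFR is truncated normal with mean 120.3 and SD ≈ 18.0
back-derived from the reported mean's 95% CI for n = 14 (SE = half-width /
t₁₃; a reconstruction, not a reported value), truncated to [60, 180].
Weight, age and sex are sampled to match the cohort summaries but are
unused by the model — they exercise the data-format path only. The
generator emits the full 14×7 = 98-observation grid (the clinical dataset
had 96 after two unexplained exclusions). It does not simulate assay
drift, sampling-time error, haemolysis, or informative dropout — so
passing recovery tests demonstrate correctness of the estimator under the
model, not robustness to real-data artefacts.

## Reproducibility and numerics

All randomness flows through numpy Generators seeded from user-supplied
integers; per-subject substreams are spawned from a root SeedSequence so
datasets are bit-reproducible and regimen comparisons share draws. Units
are fixed throughout (hours, mg, mg/L, L/h); no unit inference. Predicted
concentrations are floored at 1e-10 inside likelihoods; log-error SDs at
1e-8; MH proposal scales clipped to [0.01, 5].

## Known limitations

* The published clinical estimates themselves (Table-level point
  estimates, sample exposure medians, clinical MAPE) are not reproducible
  without the raw concentration data; they are covered by
  parameter-recovery and property tests on synthetic data instead.
* PTA is evaluated at steady state only; the initial 48 h of therapy and
  loading-dose strategies are out of scope (all regimens are
  maintenance-only from t = 0).
* No inter-occasion variability, no covariates on Q/V1/V2, no MIC
  distribution, no nephrotoxicity risk model above AUC 650.
* The Cmin-index SHAP ordering discussed above differs from the source
  figure's emphasis; see the attribution section.
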