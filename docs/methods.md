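# Methods

## Pharmacokinetic model

Daptomycin disposition is modeled as a linear two-compartment system with
zero-order IV infusion into the central compartment. The nonparametric
engine uses the micro-constant parameterization
`(V1_std, Ks, Ki, Kcp, Kpc)`:

* `V1_std` (L per 70 kg) — central volume, scaled **linearly** in body
  weight, `V1 = V1_std·WT/70`; no allometric exponent is applied because
  the population value is expressed per 70 kg.
* `Ke = Ks·(CLcr/100) + Ki` (1/h) — elimination split into a renal
  component proportional to Cockcroft–Gault creatinine clearance and a
  non-renal constant.
* `Kcp`, `Kpc` (1/h) — intercompartmental transfer.

Concentrations are computed in closed form from the disposition
eigenvalues `alpha, beta` (`alpha+beta = Ke+Kcp+Kpc`,
`alpha·beta = Ke·Kpc`): the response to a constant-rate infusion running
since time 0 is the integral of the unit-bolus biexponential, and an
arbitrary dose history is handled by superposition
`C(t) = Σ_events R·[F(τ) − F(max(0, τ−T_inf))]`. When the eigenvalues
coincide within a relative discriminant of 1e-10 the analytic confluent
limit (`e^{−λt}(1+(λ−Kpc)t)/V1` impulse response) replaces the
biexponential branch to avoid catastrophic cancellation; the two branches
agree to ~1e-6 at the switch, which the tests check explicitly.

Steady state is evaluated analytically by geometric accumulation of the
exponential terms over the dosing interval (never by simulating many
doses); `AUC24_ss = (24/interval)·dose/CL` is the linear-PK identity,
`Cmax_ss` is read at end of infusion and `Cmin_ss` at end of interval.
The repeating-interval assumption uses the *last* recorded dose as the
maintenance dose even when the recorded history is irregular; the full
history is only used for fitting. Terminal half-life is `ln 2 / beta`.

A stiff-safe piecewise `solve_ivp` integrator (`ode_oracle`) implements
the same contract independently and is used only in tests (closed form vs
oracle < 1e-6 relative over randomized parameter/regimen/time triples).

Time convention: hours, t = 0 at first dose start. Default infusion
duration is 0.5 h, configurable per dose event.

## Priors

**Nonparametric prior.** The original discrete support of the population
model is not published; only per-parameter summary moments (mean, median,
variance, CV) are. The prior is therefore reconstructed as N equally
weighted draws from independent log-normals matched to each parameter's
arithmetic mean and CV (`sigma² = ln(1+CV²)`, `mu = ln(mean) − sigma²/2`).
Log-normals keep parameters positive and right-skewed, as PK parameters
are; the posterior machinery is agnostic to how the support was obtained.
`n_support = 1` returns the means exactly; the default is 1000 points.

**Parametric prior.** Log-normal population distributions on
`(CL, V1, Q, V2)` with typical values derived from the micro-constant
moments at the reference patient (70 kg, CLcr 100 mL/min, female):
`CL = (Ks+Ki)·V1 = 0.759 L/h`, `V1 = 6.90 L`, `Q = Kcp·V1 = 4.78 L/h`,
`V2 = Q/Kpc = 7.17 L`. The covariate topology is: CLcr and sex on CL,
weight on Q and V2 (linear in WT/70 by default). The CLcr effect's
functional form must be declared in config (`linear` or `power`); the
default is the linear form implied by the renal fraction of clearance,
`1 + 0.4545·(CLcr/100 − 1)`. The sex factor defaults to 1.0 (the topology
is supported but no magnitude is assumed); users with an external
coefficient set can supply all values via config. Body temperature is
deliberately excluded from the covariate model. Default between-subject
SDs on the log scale are 0.35 (CL, V1) and 0.7 (Q, V2), reflecting the
moderate CV of volume/clearance and the much larger CV of the transfer
constants.

**Assay error.** Residual SD is polynomial in concentration,
`sigma(C) = c0 + c1·C (+ c2·C² + c3·C³)`, defaults `c0 = 0.5` mg/L (a
quarter of the 2 mg/L LLOQ) and `c1 = 0.1` (~the assay's stated ≤11%
interday precision). Both are configurable; construction rejects any
configuration with non-positive sigma on [0, 200] mg/L.

## Bayesian engines

The likelihood is Gaussian around the model prediction with SD evaluated
at the *predicted* concentration (keeps the likelihood well-defined for
near-zero observations). Observations below the LLOQ contribute the
left-tail probability `Phi((LLOQ − Cpred)/sigma)` (M3-style censoring) —
how the reference TDM tools handle BLQ values is not documented, so this
is an explicit package assumption.

* **Nonparametric posterior**: `w_j ∝ prior_j · L_j`, computed in log
  space with max-subtraction. An empty observation set returns the prior
  unchanged; if every support point underflows to zero likelihood a
  degenerate-posterior error with diagnostics is raised. No support
  pruning is performed.
* **MAP fit**: minimizes `−log L + Σ eta²/(2·omega²)` over
  `eta = log theta − log theta_typical(cov)` with L-BFGS-B from a fixed
  five-start schedule (prior mode; all parameters shifted ±1 prior SD; CL
  alone shifted ±1 SD), hence fully deterministic. Parameters with
  `omega = 0` are held fixed. Zero observations short-circuits to the
  exact prior mode. Convergence requires the finite-difference gradient
  norm below 1e-2 (scaled by the objective); failures raise an error
  carrying the best point found.

Posterior predictions are the weight-averaged concentration (NP) or the
point prediction (MAP); posterior exposure reports the per-support
steady-state table and its expectations. `E[AUC24] = daily dose · E[1/CL]`
holds by construction and is asserted in tests.

## Dose targets

Linearity makes each support point's steady-state AUC24 and Cmin exactly
proportional to the daily dose, with sensitivities `s_auc = 1/CL` and
`s_cmin` computed once per fit on a template schedule (default q24h,
0.5 h infusion). Two objectives:

* `expectation`: `D = T / E[s]` — hits the target in posterior mean;
* `mm_squared_error` (default): `D = T·E[s]/E[s²]` — minimizes the
  posterior-expected squared deviation from the target, the
  multiple-model dosage-design criterion. By Cauchy–Schwarz it never
  exceeds the expectation dose, with equality only for a degenerate
  posterior (then both equal `T/s`, which is what the MAP engine gets).

The published description names the two targets (AUC24 = 666 mg·h/L;
Cmin = 24.3 mg/L) but not the internal objective of either software
product; the default here is the standard nonparametric-control choice
and the alternative is exposed. Doses are reported continuous in mg/day
and mg/kg/day, plus a reporting-only practical dose rounded to 10 mg.
Percentile-targeting for Dmax (rather than the expectation) would be a
possible extension and is not implemented. The dosing interval is an
input, not a decision variable.

## Evaluation statistics

ME and MAPE follow the standard definitions (MAPE in percent of the
observed value); BLQ observations are excluded from prediction pairs,
with the excluded count reported, because a censored value has no point
denominator. Engine comparisons use the Wilcoxon signed-rank test for
paired quantities and Mann–Whitney otherwise — exact p-values for
n ≤ 25, normal approximation with continuity correction beyond — plus the
R² between engines. Bland–Altman analysis regresses differences on
averages; if the slope's p-value is below 0.05 (the criterion is stated
in the source literature without an explicit alpha; 0.05 is fixed here)
the reporting mode switches to regression-based limits of agreement
(fitted line ± 1.96 residual SD). Which quantities need regression-based
limits is decided per dataset by this test, not hard-coded.
Target-attainment fractions use strict inequalities (AUC24 < target;
Cmin > limit).

## Synthetic cohort

The generator emulates the monitored population: weight ~ N(76, 18²) kg
truncated at 30, CLcr ~ N(103, 56²) mL/min truncated at 10, 42.5% female,
age ~ N(62, 17²) truncated to [18, 100], all independent (only marginal
moments are reported, so no covariate correlation is imposed). True
parameters are drawn from the discrete prior's support by weight. Dosing
is q24h at `round(policy·weight)` mg with policy ~ N(7.6, 1.3²) mg/kg/day.
Sampling occurs on the 6th dose (index 5, near steady state given a
~13–17 h terminal half-life): a trough 5 min pre-dose, a sample 0.5 h
after infusion start, and one uniformly in 5–6 h post-dose, the first two
jittered ±15 min. Whether "30 min after administration" means after
infusion start or end is ambiguous in the source design; the default is
after *start*, switchable via `peak_after_infusion_end`. Observations get
Gaussian assay noise (clipped at 0) and values below 2 mg/L are censored
and flagged. The infusion duration is not reported for the original
cohort; 0.5 h is a documented default, not an inferred fact.

What the generator does *not* emulate: covariate correlations,
multi-occasion TDM, inter-occasion variability, model misspecification
(patients are generated from the same support the fitter uses), dosing
errors and recording noise of routine care. Passing recovery tests
therefore demonstrate the correctness and calibration of the estimation
machinery, not clinical predictive performance on real patients.

## Numerical choices and problem sizes

* Eigenvalue confluence threshold 1e-10 (relative discriminant).
* Posterior weights validated to sum to 1 within 1e-12.
* Exact rank tests up to n = 25.
* The test suite and the acceptance script use a 200-patient cohort with
  a 1000-point prior, 100 random triples for the oracle comparison, and
  50 patients for MAP recovery — sizes chosen so the whole suite runs in
  well under a minute of compute while keeping Monte-Carlo noise far from
  the asserted bounds.
* The end-to-end AUC24 recovery slope sits slightly below 1 (~0.85–0.9):
  posterior expectations shrink toward the prior mean under a sparse
  3-sample design, which attenuates the estimated-vs-true regression.
  This is expected behavior of a calibrated Bayesian estimator, not a
  bug; richer designs move the slope toward 1.

## Known limitations

* The reconstructed discrete prior matches published moments, not the
  original support; absolute exposure statistics of the synthetic cohort
  (e.g. mean AUC24) therefore differ from the clinical cohort's.
* The parametric engine's default coefficients are derived from the
  micro-constant moments rather than the original manufacturer model,
  whose numeric coefficients are not reproduced here; supply them via
  config if available.
* No saturable elimination, protein-binding kinetics or tissue (bone)
  compartment; no interval optimization; no MCMC for the parametric
  posterior; no inter-occasion variability.
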