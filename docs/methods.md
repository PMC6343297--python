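# Methods

This note documents the models, the estimation machinery, the
synthetic-trial generator and the numerical choices behind
`propofol_pkpd`, in the spirit of the methods documentation of mature
modelling packages.

## Structural models

**Disposition.**  Propofol kinetics follow a mammillary two-compartment
model parameterised by CL, Q, V1, V2 (L/min, L).  The micro-constants
are k10 = CL/V1, k12 = Q/V1, k21 = Q/V2, and the disposition
eigenvalues are the roots of
λ² − (k10+k12+k21)λ + k10·k21 = 0, real and negative for any positive
parameter set.  Dosing input u(t) is piecewise constant: every bolus is
a 10-s infusion, matching how induction and reinduction boluses are
administered clinically (an instantaneous bolus, duration 0, is kept
for analytic work such as the peak-time computation).  The state vector
(amounts; effect-site concentrations appended when a biophase is
attached) obeys x' = Ax + u(t)e₁, solved *exactly* by
eigen-decomposition of A and superposition of per-segment step
responses — each observation time costs a handful of `exp` evaluations
and no integration error enters the likelihood.  If the eigenvector
basis is ill-conditioned (condition number > 1e8, e.g. nearly repeated
eigenvalues), the solver falls back to matrix-exponential segment
chaining, which is exact as well.  All samples, venous and arterial,
are treated as draws from the central compartment.

**Biophase.**  The effect site is mass-less (it does not deplete the
PK states) and concentration-driven:
dCe₁/dt = ke0(Cb − Ce₁) [− ke12·Ce₁ + ke21·Ce₂ for the two-compartment
form, with dCe₂/dt = ke12·Ce₁ − ke21·Ce₂].  The measured index responds
to the **central** effect-site concentration only.  In equilibrium
Ce₁ → Cb for both forms.  The peak-time utility simulates a unit IV
bolus, scans [0, 120] min at 1-ms resolution and refines the bracketed
peak with a bounded scalar minimiser (ties resolve to the earliest
time); with the default PK and the BIS biophase constants the peak
falls at 2.63 min.

**Concentration–effect.**  Indices follow the inhibitory sigmoid Emax
model E = E0 − Emax·Ce^γ/(EC50^γ + Ce^γ).  BIS: E0 = Emax = 100, both
fixed (sparse awake data make them inestimable, so the awake baseline
and full-suppression floor are pinned to the nominal scale).  cAAI: E0
estimated, Emax parameterised as a **fraction** of E0 on the logit
scale, which enforces the floor E0 − Emax ≥ 0 by construction.

## Mixed-effects estimation

Individual parameters are log-normal, P_i = P_tv·e^{η_i},
η_i ~ N(0, ω²), diagonal Ω (no η correlations are estimated).  Residual
error is additive on the log-concentration scale for PK
(σ = 0.19 ≈ 19% proportional error at the default truth) and additive
in index units for PD (σ² in index-units²).  Concentrations below the
assay's limit of quantification (0.005 mg/L) are excluded from fitting;
at this LLOQ the information loss is negligible.

The per-subject marginal likelihood is approximated by FOCE: the
conditional mode η̂ is found by a damped Gauss–Newton search (finite
-difference Jacobian of the prediction with step 1e-4; step-halving
line search; convergence when the step drops below 1e-9), and

    −2·log L_i ≈ l₂(η̂) − q·log 2π + log det(J'J/σ² + Ω⁻¹)

where l₂ is the joint −2 log density and J = ∂f/∂η at η̂.  Because both
residual models have constant variance on their fitting scale, the
η–ε interaction term is handled exactly by evaluating residual variance
at the individual prediction.  A `laplace` option replaces the
Gauss–Newton Hessian with a full numerical Hessian of the negative log
joint; on well-behaved problems the two agree to well under one OFV
point, and both agree with an adaptive Gauss–Hermite oracle to ~0.01
points on small test problems.  With no random effects the OFV is the
exact fixed-effects −2 log likelihood.  The 2π constants are kept,
so OFV values are not comparable to conventions that drop them — only
OFV *differences* are ever interpreted, against the χ²(1) thresholds
3.8 (p<0.05) and 7.8 (p<0.005).

Fixed effects are estimated on the log scale (logit for the cAAI Emax
fraction; identity for covariate coefficients), which enforces
positivity without constrained optimisation.  The outer search is
L-BFGS-B with finite-difference gradients (step 1e-4 on the estimation
scale) and relative function tolerance 1e-9; per-subject conditional
modes are warm-started across outer iterations.  Restarts from
jittered initialisations are available (`n_restarts`, jitter seeded);
the default is a single start, which proved stable from neutral
initial values on all study-scale problems — the inner Gauss–Newton is
the main safeguard against poor linearisation points.  A subject whose
prediction fails at a trial point (non-positive concentration under
the log transform, invalid parameter combination) contributes a large
finite penalty so the search moves away rather than crashing; failure
at the initial estimates for *every* subject raises an estimation
error.

Standard errors come from the inverse numerical Hessian of the OFV
(central differences, step 1e-3): cov = 2·H⁻¹ on the estimation scale,
delta-method back-transformed; 95% CIs are symmetric on the estimation
scale.  Empirical-Bayes (post-hoc) η are conditional modes at the
final estimates; a subject with no observations gets η = 0.

**Sequential PK→PD.**  The PD fit fixes each subject's PK at its
post-hoc individual values (the IPP approach): biophase and Emax fixed
effects, their ω², and σ² are then estimated against the index data.
η are estimated on EC50, γ and ke0 (the parameters with reported IIV);
ke12/ke21 and the fixed E0/Emax carry none.

**Reported variability.**  IIV is reported as
CV% = 100·√(exp(ω²) − 1), the log-normal conversion (0.059 → 25%,
0.159 → 42%, 0.952 → 126%).  Note one internal inconsistency in this
convention's source tables: the CV printed for the BIS Hill
coefficient (34%) matches √ω² = √0.117 rather than the footnote
formula (35.2%); the package implements the footnote formula
uniformly — the difference is cosmetic at these magnitudes.

## Covariate analysis

Bodyweight, age, sex and the remifentanil infusion rate (summarised
per subject as its maintenance rate in mcg·kg⁻¹·min⁻¹) are screened by
linear regression of post-hoc η on each covariate (slope, Pearson r,
p-value; constant covariates are reported as missing, not dropped).
For formal testing a covariate enters one parameter at a time as
linear-normalised-to-median, power-normalised-to-median, or a
fractional shift for sex; the extension is refit from the base optimum
and retained only if ΔOFV ≥ 7.8 **and** the coefficient's 95% CI
excludes 0.  Threshold comparisons are inclusive at exactly 3.8/7.8.
No automated stepwise search is provided (covariates are tested
separately, as in the source study).

## Model evaluation

**Bootstrap.**  Subjects are resampled with replacement (same trial
size, no stratification), each replicate refit starting from the
original estimates; non-converged replicates are excluded and counted.
Summaries are the replicate mean and CV% per parameter.  Defaults are
scaled to desk hardware (50 replicates); the reference settings of the
emulated study (1000 PK / 250 PD) are a parameter away.

**NPDE.**  For each subject, n_sim replicate observation vectors are
simulated under the fitted model (drawing η and ε); observed and
simulated vectors are decorrelated with the Cholesky factor of the
empirical simulation covariance (ridge-regularised with a logged flag
if singular); each decorrelated observation's rank among its
decorrelated simulations, clipped by 1/(2·n_sim) to avoid 0/1, maps
through Φ⁻¹ to the NPDE.  Rank ties are broken by seeded uniform
jitter.  Under the true model the NPDE are approximately N(0,1)
(checked by Kolmogorov–Smirnov); n_sim defaults to 1000 for reference
runs, 300 for quick checks.

**GOF tables.**  Diagnostics are tabular: observed, individual
prediction (post-hoc η), population prediction (η = 0) and weighted
residual (obs − population prediction)/σ on the fitting scale.
Plotting is deliberately out of scope; the tables feed any plotting
front-end.

## Synthetic trial generator

The generator emulates a 14-adolescent scoliosis-surgery trial with an
intraoperative wake-up test:

- **Covariates**: weight and age from scaled Beta distributions matched
  to median 51 kg (36.6–82) and 14.7 y (9.8–20.1); sex 2:12 M:F;
  remifentanil maintenance rate uniform 0.2–1.0 mcg·kg⁻¹·min⁻¹.
- **Dosing**: 4 mg/kg induction bolus over 10 s; maintenance infusion
  uniform within 2–10 mg·kg⁻¹·h⁻¹, piecewise-constant with 1–3 random
  adjustment times; total infusion duration Beta-matched to median
  410 min (200–460).  The wake-up stop starts at 45–65% of the
  infusion duration and lasts a Beta-matched median 21.5 min
  (7.6–42.4); reinduction is a 3–5 mg/kg bolus.  Dose titration is
  *random within the protocol range*, not feedback-controlled: the
  attending anesthesiologist was blinded to the indices, so dosing is
  exogenous to the PD signal.
- **Blood sampling** follows the clinical template (pre-induction;
  early venous samples at 15/30 min; scheduled arterial samples;
  around the wake-up stop and movement; before and 1 h after each dose
  adjustment and the reinduction; before the final stop; three
  emergence samples), capped at 25 samples — about 15 per subject, of
  which the pre-induction one is below LOQ by construction.
- **Indices** are observed every 4 min from the pre-induction awake
  baseline: cAAI until the end of infusion, BIS also through emergence
  (return of consciousness Beta-matched to median 52 min), giving
  median counts near 113 (BIS) and 100 (cAAI) per subject.
- **Simulation truth** defaults to the final population estimates
  (`default_truth()`); observations add log-scale noise (σ = 0.19) to
  concentrations and additive noise (σ² = 59.5 / 133) to BIS/cAAI.
  Index observations are *not* clipped to [0, 99]: the additive error
  model is symmetric and clipping would bias estimation.

All randomness flows through one seeded generator; identical
config + seed reproduces the dataset byte-for-byte.
`generate_trial(..., return_truth=True)` also returns the realized
individual parameters for recovery experiments.

What the generator does **not** emulate: hemodynamics-guided titration
feedback, venous/arterial concentration differences, stimulus-induced
arousal during the wake-up test (the indices rise only because the
effect-site concentration falls), remifentanil kinetics, or monitor
artifacts in the 5-s index stream (the 4-min grid stands in for the
median per-patient analysis counts).  Consequently, passing recovery
tests demonstrate that the estimation machinery is consistent under
the study's design and error model — not that the model is correct for
real monitor data.

## Problem sizes and reproducibility

Recovery experiments run at the study scale: 14 subjects, ~15
concentration samples and ~115 BIS observations per subject.  A PK fit
takes seconds; the sequential BIS fit minutes on one core.  The test
suite uses reduced designs (5–8 subjects, coarser PD grids) for
model-discrimination and validation properties, chosen so each check
retains a large decision margin (e.g. ΔOFV ≈ 17 vs threshold 3.8 for
the biophase-order comparison; ΔOFV ≈ 97 vs 7.8 for the Hill-steepness
comparison).

At n = 14 the geometric-mean EC50 of a drawn trial has ~6.5% sampling
variability (ω² = 0.059), so single-seed recovered values scatter
around the population truth by design; the estimator tracks the
*realized* trial mean closely.  `scripts/acceptance.py` therefore runs
the full-scale pipeline on three independent replicate trials (seeds
derived from one master seed) and reports the median recovered values,
the central recovery quantity the experiment is about.

## Known limitations

- FOCE linearisation bias is not corrected; for the steep cAAI Hill
  coefficient (γ ≈ 6.85) the likelihood surface is hard and fits are
  slower and more sensitive to initial values than for BIS.
- η correlations, inter-occasion variability and nonlinear elimination
  are not modelled (none were reported for this setting).
- CIs are Wald-type on the estimation scale; profile-likelihood or
  bootstrap CIs are the alternative where Wald intervals are doubtful.
- The CLI covers the PK-side bootstrap/NPDE; PD-side evaluation runs
  through the library API, where post-hoc PK attachment is explicit.
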