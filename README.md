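# propofol-pkpd

Population pharmacokinetic-pharmacodynamic (PK-PD) modelling of propofol
anesthesia, built around the setting of adolescent idiopathic-scoliosis
surgery with an intraoperative wake-up test: induction bolus, titrated
maintenance infusion, a mid-surgery infusion stop while the patient is
woken, reinduction, and emergence.  The package is aimed at
pharmacometricians and anesthesia researchers who want a self-contained,
tested implementation of the full analysis pipeline — structural models,
nonlinear mixed-effects estimation, covariate testing, bootstrap and
NPDE validation — together with a synthetic-trial generator that
reproduces the statistical structure of such a study, so every stage can
be exercised without patient data.

## The model

**Pharmacokinetics.**  A two-compartment disposition model parameterised
by clearance CL, inter-compartmental clearance Q and volumes V1/V2
(units L/min and L; time in minutes).  Dosing is piecewise-constant
(boluses are 10-s infusions) and the linear system is solved exactly by
eigen-decomposition, so no ODE integration error enters the likelihood.

**Biophase.**  The measured effect lags the blood concentration Cb; a
mass-less effect compartment equilibrates as

    dCe/dt = ke0 (Cb − Ce)

optionally extended with a peripheral effect compartment (rates ke12,
ke21) representing drug redistribution within the brain.  The
two-compartment biophase is the default for BIS, the classical
one-compartment form for cAAI.

**Concentration-effect.**  Depth-of-anesthesia indices follow an
inhibitory sigmoid Emax model driven by the central effect-site
concentration Ce:

    E(Ce) = E0 − Emax · Ce^γ / (EC50^γ + Ce^γ)

For BIS both E0 and Emax are fixed at 100; for cAAI the baseline E0 is
estimated and Emax is parameterised as a fraction of E0.

**Mixed effects.**  Individual parameters are log-normal,
P_i = P_tv·exp(η_i) with η_i ~ N(0, ω²); residual error is proportional
on the log scale for concentrations (Y = log c_pred + ε) and additive in
index units for BIS/cAAI.  The population objective function (OFV,
−2 log marginal likelihood) is approximated per subject by FOCE
(linearisation at the conditional mode of η) with a Laplace option, and
minimised by a quasi-Newton search on log-transformed parameters.
PK and PD are fitted **sequentially**: the PD fit fixes each subject's
PK at its empirical-Bayes (post-hoc) values.  Nested models are
compared by OFV differences against the χ²(1) thresholds 3.8 (p<0.05,
model building) and 7.8 (p<0.005, covariate retention, additionally
requiring the extra coefficient's 95% CI to exclude 0).

## Worked example

```python
from propofol_pkpd import (
    PopulationModel, generate_trial, pk_model_spec, bis_pd_spec,
    fit_sequential_pd,
)

trial = generate_trial(seed=1)                    # 14-subject synthetic study
pk_fit = PopulationModel(trial, pk_model_spec()).fit(compute_se=False)
print(f"CL = {pk_fit.params['CL']:.3f} L/min, "
      f"IIV CV = {pk_fit.cv_percent()['CL']:.1f}%")

pd_fit = fit_sequential_pd(pk_fit, bis_pd_spec(order=2), trial,
                           compute_se=False)
print(f"BIS EC50 = {pd_fit.params['EC50']:.2f} mg/L, "
      f"gamma = {pd_fit.params['gamma']:.2f}")
```

Output from the run above:

```
CL = 1.340 L/min, IIV CV = 30.1%
BIS EC50 = 3.43 mg/L, gamma = 1.54
```

The trial was simulated with a true clearance of 1.37 L/min (22.1% CV),
a true BIS EC50 of 3.51 mg/L and a true Hill coefficient of 1.43, so
the fits recover the simulation truth to within the sampling error of
a 14-subject study.
`fit.summary()` prints the full estimate table;
`fit.bootstrap(n_reps=...)`, `fit.npde(n_sim=...)` and
`fit.gof_table()` provide the internal-validation machinery, and
`screen_covariates` / `evaluate_covariate_inclusion` implement the
covariate analysis.

A command-line interface mirrors the pipeline
(`propofol-pkpd simulate | fit-pk | fit-pd | covariates | bootstrap |
npde | report`); each command writes CSV/JSON artifacts plus a run log
with the seed and config hash.

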