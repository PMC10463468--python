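# lungtraj

Joint modelling of lung-function trajectories in progressive fibrosing
lung disease, for irregular pulmonary-function-test data in which *when*
a patient is measured and *how long* they stay under follow-up both carry
information about the trajectory itself.

## The problem

In registries of idiopathic pulmonary fibrosis (IPF), FVC and DLco
% predicted are collected during routine care: sicker patients are tested
more often, and follow-up ends in terminal events (death, transplant,
hospice entry, withdrawal due to worsening) that depend on lung function.
Ordinary mixed models assume neither of these, and attenuate the estimated
rate of decline because the surviving, still-measured population grows
healthier over time.  `lungtraj` is for biostatisticians and respiratory
researchers who need trajectory estimates that stand up to both mechanisms.

## The model

Each patient carries shared random effects `u ~ N(0, σ²_u)` and
`v ~ N(0, σ²_v)` linking three sub-models:

| sub-model | form |
|---|---|
| visit process | intensity `λ₀(t)·exp(α'x + u)` (piecewise-constant `λ₀`) |
| longitudinal | `Y(t) = β'x + (δ + θ'x)·t + γ₁u + v + ε`, `ε ~ N(0, σ²_e)` |
| terminal event | hazard `h₀(t)·exp(φ'x + γ₂u + γ₃v)` (piecewise-constant `h₀`) |

`γ₁ < 0`: lower values go with more frequent testing; `γ₂ > 0`: frequent
testing goes with higher event risk; `γ₃ < 0`: lower values raise the
hazard.  The likelihood integrates the product of the three conditional
likelihoods over `(u, v)` by adaptive Gauss–Hermite quadrature and is
maximized with L-BFGS-B; see `docs/methods.md` for details, assumptions
and limitations.

Because registry data of this kind are not redistributable, the package
ships a synthetic-cohort generator whose reference parameter sets encode
fitted registry estimates (FVC: δ = −2.8 %/yr, σ²_u = 0.53,
σ²_v = 163.88, γ₁ = −14.05, γ₂ = 5.73, γ₃ = −0.033; analogous DLco set) as
generative truth, plus a recovery harness that refits simulated cohorts
against that truth.

## Worked example

```python
import numpy as np
from lungtraj import JointTrajectoryModel, fvc_reference_params, simulate_cohort

truth = fvc_reference_params()                      # generative "registry truth"
cohort = simulate_cohort(truth, n=300, rng=np.random.default_rng(0))
print(f"{len(cohort.measurements)} FVC measurements from 300 patients; "
      f"{int(cohort.baseline['event'].sum())} terminal events")

model = JointTrajectoryModel().fit(cohort.measurements, cohort.baseline)
p = model.params_
print(f"annual decline : {model.annual_decline_:.2f} % predicted per year "
      f"(SE {model.result_.se_for('delta'):.2f})")
print(f"sigma2_u = {p.sigma2_u:.2f}   sigma2_v = {p.sigma2_v:.1f}")
print(f"gamma1 = {p.gamma1:.1f}   gamma2 = {p.gamma2:.2f}   gamma3 = {p.gamma3:.3f}")
```

prints

```
1007 FVC measurements from 300 patients; 115 terminal events
annual decline : 2.75 % predicted per year (SE 0.23)
sigma2_u = 0.52   sigma2_v = 121.6
gamma1 = -13.5   gamma2 = 6.00   gamma3 = -0.004
```

The fitted annual decline (2.75 %/yr, truth 2.8) and frailty variance
(0.52, truth 0.53) are recovered within sampling error; the association
signs match the generative mechanism (more tests ↔ lower values ↔ higher
event risk).  At n = 300 the weakly identified `γ₃` is noisy — the
20-replicate harness at n = 500 (below) is the calibrated check.

Covariates enter by name (`covariates=`, `interactions=`,
`visit_covariates=`, `hazard_covariates=`; use
`lungtraj.encode_covariates` for categorical ones), and
`estimate_mean_trajectory` turns a fit into daily mean curves with
subgroup intercept/slope contrasts.  `BaselineValueTrajectoryModel` fits
the modified model in which the enrolment measurement predicts the
subsequent slope.  `fcs_impute`/`pool_rubin` handle missing baseline
covariates by chained-equations multiple imputation.

The same stages are scriptable from the shell:

```bash
lungtraj simulate --n 500 --seed 1 --out cohort/
lungtraj fit --measurements cohort/measurements.csv --baseline cohort/baseline.csv --out fit/
lungtraj recover --measure fvc --n 500 --replicates 20 --seed 1 --out recovery/
lungtraj pipeline --config config.yaml
```

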