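# Methods

## The problem

Lung function in idiopathic pulmonary fibrosis (IPF) is tracked with
repeated pulmonary function tests — FVC and DLco, expressed as % of a
demographic reference prediction — collected during routine care rather
than on a fixed schedule.  Two features of such data break ordinary
repeated-measures models:

1. **Informative measurement times.** Sicker patients are tested more
   often, so the observed values over-represent low trajectories.
2. **Dependent terminal events.** Follow-up ends in death, transplant,
   hospice entry or withdrawal due to worsening disease, all related to the
   trajectory itself; survivors at any time are a healthier-than-average
   subset.

A naive linear mixed model therefore attenuates the estimated decline (the
package's test suite demonstrates this against `statsmodels` `MixedLM`).

## The model

Each patient *i* carries two shared random effects, a measurement-process
frailty `u_i ~ N(0, sigma2_u)` and a longitudinal random intercept
`v_i ~ N(0, sigma2_v)`, linking three sub-models:

* **Visit process** — measurements arrive as an inhomogeneous Poisson
  process with intensity `lambda0(t) * exp(alpha'x_i + u_i)`, with
  `lambda0` piecewise-constant on a knot grid.
* **Longitudinal values** — at visit time `t` (years),
  `Y_ij = beta'x_i + (delta + theta'x_i) * t + gamma1*u_i + v_i + eps_ij`,
  `eps ~ N(0, sigma2_e)`.  Polynomial time terms (`time_degree > 1`) can be
  added to test linearity.  A random slope (`sigma2_w`) is available in the
  simulator but is not estimated.
* **Terminal events** — proportional hazards
  `h0(t) * exp(phi'x_i + gamma2*u_i + gamma3*v_i)` with piecewise-constant
  `h0`, right-censored administratively.

The associations have direct interpretations: `gamma1 < 0` — patients with
lower values are tested more often; `gamma2 > 0` — frequent testing goes
with higher terminal-event risk; `gamma3 < 0` — lower values raise the
hazard.  `gamma3` multiplies the random intercept (a value-scale quantity)
rather than the current mean: at magnitudes of a few hundredths per
% predicted this is the only scale on which the coefficient is plausible.

Withdrawal for reasons other than worsening disease is treated as
independent right-censoring; only the worsening-related composite is a
terminal event.

## Likelihood and estimation

Conditional on `(u, v)` the three sub-model likelihoods multiply; the
patient contribution is the double integral of that product against the
two normal densities.  Both baseline functions being piecewise-constant
makes every time integral closed-form, so the conditional log-likelihood
reduces to a handful of per-patient sufficient statistics (visit counts
and exposures per piece, residual sums) and the integrand is strictly
log-concave in `(u, v)`.

The integral is evaluated by **adaptive Gauss-Hermite quadrature**
(default 9 nodes per dimension): a damped Newton iteration, vectorized
across patients with analytic gradients and Hessians, locates each
patient's posterior mode and curvature, and the product-Hermite grid is
recentred and rescaled accordingly.  On a five-patient toy at moderate
association values the log-likelihood changes by less than 1e-4 between 7
and 15 nodes; at the heavy-tailed reference associations (`gamma2` near 6)
convergence is slower but stable to a few parts in 1e3 at the default node
count, and the value agrees with plain Monte-Carlo integration (100k prior
draws) within Monte-Carlo error.  Degenerate variances (`sigma2 = 0`)
collapse the corresponding dimension exactly.

Maximization uses L-BFGS-B on a transformed vector (variances on the log
scale) with finite-difference gradients.  Starting values are
data-informed: OLS for the fixed effects, occurrence/exposure rates for
the baseline pieces, a within/between residual decomposition for
`sigma2_e`/`sigma2_v`, 0.3 for `sigma2_u` and zero for all three
associations.  Convergence requires a relative objective change below
1e-10 at projected-gradient norm 1e-3; a single restart with fresh
curvature memory is attempted if the first pass stops abnormally.  The fit
is deterministic given data, initial values and tolerances.  Standard
errors come from a central-difference observed information matrix
(delta-method back-transform for the variances); Wald chi-square tests per
covariate (joint across dummy columns of a categorical covariate) test the
covariate-by-time interactions, and main-effect p-values are reported when
the interaction is not significant at the 5% level.  No multiplicity
adjustment is applied.

Default knot grids are a single piece (constant baseline intensity and
hazard).  This matches the synthetic reference conditions and keeps the
recovery harness's parameter count minimal; multi-piece grids are fully
supported (`visit_knots`/`hazard_knots`) and a splitting invariance is
tested.  Quantiles use linear interpolation everywhere; a month is
30.4375 days and a year 365.25 days.

## The synthetic cohort generator

Registry data of this kind cannot be redistributed, so the generator is
the package's test bed.  Its reference parameter sets encode the fitted
registry estimates as generative truth:

| parameter | FVC | DLco | role |
|---|---|---|---|
| intercept | 72.9 | 42.5 | enrolment % predicted (cohort median) |
| delta | -2.8 | -2.9 | slope, % predicted per year |
| sigma2_u | 0.53 | 0.45 | visit-frailty variance |
| sigma2_v | 163.88 | 88.19 | random-intercept variance |
| gamma1 | -14.05 | -10.44 | tests <-> values |
| gamma2 | 5.73 | 5.78 | tests <-> terminal events |
| gamma3 | -0.033 | -0.050 | values <-> terminal events |

Quantities the registry analysis does not print were fixed once from the
cohort descriptives: constant baseline visit intensity 2.4/yr and hazard
0.08/yr (reproducing a median of about 4 measurements per patient,
4-5-month test intervals and roughly a third of patients reaching the
terminal composite), residual SD 5 (FVC) and 4 (DLco) % predicted —
ordinary test-retest noise on the % predicted scale — and administrative
censoring uniform on 18-48 months (median follow-up near 3 years among
event-free patients).  Visit times are drawn by piecewise inversion of the
cumulative intensity, event times by inversion of the cumulative hazard;
both are cross-checked against independent thinning and fine-grid
discrete-hazard simulators.

The generator emulates irregular, frailty-driven visit timing, shared-
effect dependence between the three processes, and dependent truncation of
follow-up.  It does **not** emulate acute-exacerbation jumps, time-varying
treatment, multi-centre clustering, or between-covariate correlation in
the registry-like covariate table; passing recovery tests therefore show
the estimator is consistent and calibrated *under the stated model*, not
that the model is correct for any particular registry.

One behaviour of the generator worth knowing when writing checks against
it: marginal per-patient visit counts are confounded by exposure
truncation (high-frailty patients are tested more per unit time but die
earlier), so association checks condition on an equal exposure window.

### Modified (baseline-value) model

For the analysis with the enrolment measurement as a predictor, the truth
pins only the slope function `slope(b) = -(2.5 + 0.02*(b - 60))` %/yr.
The enrolment value is drawn around the cohort median (SD 12.8), entered
noise-free as the predictor (the estimand is defined in terms of the
*measured* enrolment value), and the remaining parameters follow the FVC
set except `sigma2_v = 40` and `gamma1 = -7`, smaller because the
enrolment value absorbs most of the between-patient level spread.  The
fitted model centres the enrolment value and reports the slope as a linear
function of it.

## Multiple imputation

Missing baseline covariates are imputed by fully conditional specification:
per variable, a conditional model (linear for continuous, L2-regularized
logistic/multinomial for binary/categorical — the penalty also stabilizes
perfect separation) is refit each cycle on a bootstrap resample of the
observed cases, which propagates parameter uncertainty uniformly across
model types.  Defaults are m = 5 imputations and 10 cycles — standard FCS
practice; both are configurable.  Imputation models use the other baseline
covariates as predictors; longitudinal outcomes are not used (a documented
departure from fully congenial imputation).  Fits across imputations are
combined by Rubin's rules (pooled variance `W + (1 + 1/m) B`).

## Numerical choices and edge cases

* `exp` arguments are capped at 700 and Hessian diagonals clamped negative
  so catastrophic optimizer trial points return a finite penalty instead of
  NaN; cached per-patient modes are reset when non-finite or implausibly
  large (|mode| > 50).
* Baseline-measurement selection: closest to enrolment within +/-30 days,
  equidistant ties resolved to the *pre-enrolment* record so post-enrolment
  treatment cannot influence the baseline.
* Daily means for the descriptive cubic pool all values observed on a
  calendar day (patients with multiple same-day tests are not averaged
  first); the cubic is ordinary least squares on one point per day.
* Patients with zero measurements contribute the visit-process void
  probability and their survival term; they are retained.
* A variance that is exactly zero is handled by collapsing the quadrature
  dimension, not by a limiting approximation.

## Problem sizes used in the checks

The recovery harnesses simulate 20 replicates of 500-patient cohorts per
measure (about 1,800 measurements each); the Wald-calibration study uses
200 null replicates of 300 patients; oracle comparisons use 5-patient
toys with 1e5 Monte-Carlo draws.  These sizes give Monte-Carlo error
comfortably below the recovery tolerances (the replicate SD of the fitted
slope at n = 500 is about 0.18 %/yr, so its 20-replicate mean has SE about
0.04).

## Known limitations

* Time-dependent covariates are not supported; covariates are enrolment
  values only.
* The terminal composite is treated as a single event type (no competing
  risks decomposition), and `sigma2_v` maps to the random intercept only.
* The Wald information matrix is numerically differentiated; near-boundary
  variance estimates can make single-replicate standard errors slightly
  anticonservative at moderate n (the type-I-error check bounds the
  practical impact).
* GLI-2012 and DLco reference-equation coefficient tables are not bundled;
  `ReferenceModel` plug-ins (constant and log-linear file-backed
  implementations are provided) supply predicted values.
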