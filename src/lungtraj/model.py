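"""Maximum-likelihood fitting of the joint trajectory model.

:class:`JointTrajectoryModel` follows the scikit-learn estimator
conventions (constructor parameters mirror attributes, ``fit`` returns
``self``, fitted attributes carry a trailing underscore,
``get_params``/``set_params`` work) except that ``fit`` takes the two
cohort tables — a long measurement table and a per-patient table — rather
than a single design matrix.

Estimation maximizes the adaptive Gauss-Hermite likelihood with L-BFGS-B
over a transformed parameter vector (variances on the log scale), starting
from data-informed values: ordinary least squares for the fixed effects,
occurrence/exposure rates for the baseline intensity and hazard pieces, a
within/between decomposition for the variance components, and zero for the
association loadings.  Standard errors come from the numerically
differentiated observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import pinvh
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .cohort import DAYS_PER_YEAR, Measure
from .likelihood import (CompiledCohort, ModelSpec, _loglik_compiled,
                         compile_cohort)
from .params import JointModelParams

__all__ = [
    "JointTrajectoryModel",
    "BaselineValueTrajectoryModel",
    "JointFitResult",
    "TrajectoryEstimate",
    "ModelSpec",
    "encode_covariates",
    "fit_joint_model",
    "fit_baseline_value_model",
    "wald_interaction_tests",
    "estimate_mean_trajectory",
]

#: reference levels used when dummy-coding the registry covariates
REFERENCE_LEVELS = {
    "sex": "female",
    "race_ethnicity": "other",
    "diagnostic_criteria": "definite",
    "oxygen_use": "none",
}


def encode_covariates(baseline: pd.DataFrame,
                      columns: Sequence[str]) -> tuple[pd.DataFrame, dict]:
    """Dummy-code categorical covariates with documented reference levels.

    Returns the augmented table and a mapping from covariate name to the
    list of numeric columns that represent it (used for joint Wald tests
    of multi-level covariates).  Numeric and boolean columns pass through
    as single-column groups; boolean columns become 0/1 floats.
    """
    out = baseline.copy()
    groups: dict[str, list[str]] = {}
    for col in columns:
        series = baseline[col]
        if series.dtype == bool or set(series.dropna().unique()) <= {True, False}:
            out[col] = series.astype(float)
            groups[col] = [col]
        elif pd.api.types.is_numeric_dtype(series):
            groups[col] = [col]
        else:
            levels = sorted(series.dropna().unique())
            ref = REFERENCE_LEVELS.get(col, levels[0])
            dummy_cols = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{col}__{lev}"
                out[name] = (series == lev).astype(float)
                dummy_cols.append(name)
            groups[col] = dummy_cols
    return out, groups


# ---------------------------------------------------------------------------
# fit result containers
# ---------------------------------------------------------------------------

@dataclass
class JointFitResult:
    """Estimates, uncertainty and diagnostics of one joint-model fit."""

    params: JointModelParams
    b_long: np.ndarray                # full longitudinal coefficient vector
    names: list[str]
    estimates: np.ndarray             # natural scale, aligned with names
    se: np.ndarray                    # natural scale (delta method)
    cov_transformed: np.ndarray       # covariance on the optimizer scale
    loglik: float
    converged: bool
    n_iter: int
    n_evaluations: int
    trace: np.ndarray                 # log-likelihood at accepted steps
    spec: ModelSpec
    n_patients: int
    n_measurements: int
    n_excluded: int = 0
    message: str = ""
    wald: Optional[pd.DataFrame] = None
    groups: dict = field(default_factory=dict)

    @property
    def annual_decline(self) -> float:
        """Estimated mean decline in % predicted per year (positive)."""
        return -self.params.delta

    def se_for(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def estimate_for(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def parameter_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.names,
            "estimate": self.estimates,
            "se": self.se,
        })


@dataclass
class TrajectoryEstimate:
    """Estimated mean % predicted per day of follow-up.

    ``groups`` maps subgroup labels to daily mean curves; ``intercepts``
    and ``slopes`` give the day-0 level and the per-year slope of each
    curve (for a linear-in-time model the curves are exact lines).
    """

    days: np.ndarray
    overall: np.ndarray
    groups: dict
    intercepts: dict
    slopes: dict

    def intercept_difference(self, a: str, b: str) -> float:
        return float(self.intercepts[a] - self.intercepts[b])

    def slope_difference(self, a: str, b: str) -> float:
        return float(self.slopes[a] - self.slopes[b])


# ---------------------------------------------------------------------------
# optimizer parameter transform
# ---------------------------------------------------------------------------

class _FitLayout:
    """Maps the transformed optimizer vector to model parameters.

    Order: log baseline intensity pieces, visit covariates, log sigma2_u,
    longitudinal coefficients (intercept, mains, time, polynomial time,
    interactions), gamma1, log sigma2_v, log sigma2_e, log baseline hazard
    pieces, hazard covariates, gamma2, gamma3.
    """

    def __init__(self, spec: ModelSpec, long_names: Sequence[str]):
        self.spec = spec
        self.p_long = len(long_names)
        names: list[str] = []
        names += [f"log_lambda0[{i}]" for i in range(len(spec.visit_knots))]
        names += [f"alpha:{c}" for c in spec.visit_covariates]
        names += ["sigma2_u"]
        names += list(long_names)
        names += ["gamma1", "sigma2_v", "sigma2_e"]
        names += [f"log_h0[{i}]" for i in range(len(spec.hazard_knots))]
        names += [f"phi:{c}" for c in spec.hazard_covariates]
        names += ["gamma2", "gamma3"]
        self.names = names
        self.is_log_variance = np.array(
            [n in ("sigma2_u", "sigma2_v", "sigma2_e") for n in names])
        self.n = len(names)
        k_vis = len(spec.visit_knots)
        p_vis = len(spec.visit_covariates)
        self.sl_lambda = slice(0, k_vis)
        self.sl_alpha = slice(k_vis, k_vis + p_vis)
        self.i_s2u = k_vis + p_vis
        self.sl_long = slice(self.i_s2u + 1, self.i_s2u + 1 + self.p_long)
        i = self.i_s2u + 1 + self.p_long
        self.i_g1, self.i_s2v, self.i_s2e = i, i + 1, i + 2
        i += 3
        k_haz = len(spec.hazard_knots)
        p_haz = len(spec.hazard_covariates)
        self.sl_h0 = slice(i, i + k_haz)
        self.sl_phi = slice(i + k_haz, i + k_haz + p_haz)
        self.i_g2 = i + k_haz + p_haz
        self.i_g3 = self.i_g2 + 1
        # indices of beta/delta/theta inside the longitudinal block
        n_cov = len(spec.covariates)
        self.b_beta = slice(0, 1 + n_cov)
        self.b_delta = 1 + n_cov
        self.b_theta = slice(self.p_long - len(spec.interactions), self.p_long)

    def pack(self, params: JointModelParams, b_long: np.ndarray) -> np.ndarray:
        psi = np.empty(self.n)
        psi[self.sl_lambda] = params.log_lambda0
        psi[self.sl_alpha] = params.alpha
        psi[self.i_s2u] = np.log(params.sigma2_u)
        psi[self.sl_long] = b_long
        psi[self.i_g1] = params.gamma1
        psi[self.i_s2v] = np.log(params.sigma2_v)
        psi[self.i_s2e] = np.log(params.sigma2_e)
        psi[self.sl_h0] = params.log_h0
        psi[self.sl_phi] = params.phi
        psi[self.i_g2] = params.gamma2
        psi[self.i_g3] = params.gamma3
        return psi

    def unpack(self, psi: np.ndarray) -> tuple[JointModelParams, np.ndarray]:
        b_long = psi[self.sl_long].copy()
        params = JointModelParams(
            log_lambda0=psi[self.sl_lambda].copy(),
            alpha=psi[self.sl_alpha].copy(),
            sigma2_u=float(np.exp(psi[self.i_s2u])),
            beta=b_long[self.b_beta].copy(),
            delta=float(b_long[self.b_delta]),
            theta=b_long[self.b_theta].copy(),
            gamma1=float(psi[self.i_g1]),
            sigma2_v=float(np.exp(psi[self.i_s2v])),
            sigma2_e=float(np.exp(psi[self.i_s2e])),
            log_h0=psi[self.sl_h0].copy(),
            phi=psi[self.sl_phi].copy(),
            gamma2=float(psi[self.i_g2]),
            gamma3=float(psi[self.i_g3]),
            visit_knots=np.asarray(self.spec.visit_knots),
            hazard_knots=np.asarray(self.spec.hazard_knots),
        )
        return params, b_long

    def natural(self, psi: np.ndarray) -> np.ndarray:
        nat = psi.copy()
        nat[self.is_log_variance] = np.exp(nat[self.is_log_variance])
        return nat

    def jacobian_diag(self, psi: np.ndarray) -> np.ndarray:
        jac = np.ones(self.n)
        jac[self.is_log_variance] = np.exp(psi[self.is_log_variance])
        return jac


def _initial_psi(compiled: CompiledCohort, layout: _FitLayout) -> np.ndarray:
    """Data-informed starting values on the transformed scale."""
    spec = compiled.spec
    psi = np.zeros(layout.n)
    # occurrence / exposure rates per piece
    exp_vis = compiled.E_vis.sum(axis=0)
    cnt_vis = compiled.C_vis.sum(axis=0)
    psi[layout.sl_lambda] = np.log(
        np.maximum(cnt_vis, 0.5) / np.maximum(exp_vis, 1e-8))
    exp_haz = compiled.E_haz.sum(axis=0)
    cnt_haz = np.bincount(compiled.idx_haz, weights=compiled.d,
                          minlength=len(spec.hazard_knots))
    psi[layout.sl_h0] = np.log(
        np.maximum(cnt_haz, 0.5) / np.maximum(exp_haz, 1e-8))
    # OLS for the longitudinal fixed effects
    b0, *_ = np.linalg.lstsq(compiled.X_long, compiled.y, rcond=None)
    psi[layout.sl_long] = b0
    # within/between residual decomposition
    r = compiled.y - compiled.X_long @ b0
    n_pat = compiled.n_patients
    n_i = np.maximum(compiled.n_visits, 1.0)
    means = np.bincount(compiled.pidx, weights=r, minlength=n_pat) / n_i
    ssw = np.sum((r - means[compiled.pidx]) ** 2)
    df_w = max(len(r) - np.count_nonzero(compiled.n_visits), 1)
    s2e = max(ssw / df_w, 1.0)
    with_visits = compiled.n_visits > 0
    s2v = max(np.var(means[with_visits]) - s2e * np.mean(1.0 / n_i[with_visits]),
              1.0) if with_visits.sum() > 1 else 1.0
    psi[layout.i_s2e] = np.log(s2e)
    psi[layout.i_s2v] = np.log(s2v)
    psi[layout.i_s2u] = np.log(0.3)
    # gamma1, gamma2, gamma3 and covariate effects on rates start at 0
    return psi


def _numeric_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; fun is the scalar objective."""
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    hess = np.empty((n, n))
    f0 = fun(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n); e[i] = h[i]
        fp[i] = fun(x + e)
        fm[i] = fun(x - e)
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / (h[i] * h[i])
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (
                (fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm)
                / (2.0 * h[i] * h[j]))
    return hess


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class JointTrajectoryModel(BaseEstimator):
    """Joint model for lung-function trajectories under informative
    measurement times and dependent terminal events.

    Parameters
    ----------
    covariates, interactions, visit_covariates, hazard_covariates :
        numeric column names of the per-patient table entering the
        longitudinal mean, the covariate-by-time interactions and the two
        log-linear event predictors.
    visit_knots, hazard_knots :
        knot grids (years, starting at 0) of the piecewise-constant
        baseline intensity and hazard.
    time_degree :
        polynomial degree of the time trend (1 = linear).
    n_quad :
        Gauss-Hermite nodes per random-effect dimension.
    measure :
        restrict the fit to one measure ("FVC"/"DLCO"); None uses all rows.
    compute_se :
        whether to differentiate the observed information for standard
        errors and Wald tests after optimization.
    """

    def __init__(self, covariates: Sequence[str] = (),
                 interactions: Sequence[str] = (),
                 visit_covariates: Sequence[str] = (),
                 hazard_covariates: Sequence[str] = (),
                 visit_knots: Sequence[float] = (0.0,),
                 hazard_knots: Sequence[float] = (0.0,),
                 time_degree: int = 1,
                 n_quad: int = 9,
                 measure: Optional[str] = None,
                 max_iter: int = 300,
                 gtol: float = 1e-3,
                 ftol: float = 1e-10,
                 compute_se: bool = True,
                 init: Optional[JointModelParams] = None):
        self.covariates = tuple(covariates)
        self.interactions = tuple(interactions)
        self.visit_covariates = tuple(visit_covariates)
        self.hazard_covariates = tuple(hazard_covariates)
        self.visit_knots = tuple(visit_knots)
        self.hazard_knots = tuple(hazard_knots)
        self.time_degree = time_degree
        self.n_quad = n_quad
        self.measure = measure
        self.max_iter = max_iter
        self.gtol = gtol
        self.ftol = ftol
        self.compute_se = compute_se
        self.init = init

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            covariates=self.covariates, interactions=self.interactions,
            visit_covariates=self.visit_covariates,
            hazard_covariates=self.hazard_covariates,
            visit_knots=self.visit_knots, hazard_knots=self.hazard_knots,
            time_degree=self.time_degree,
        )

    def fit(self, measurements: pd.DataFrame, baseline: pd.DataFrame,
            groups: Optional[dict] = None) -> "JointTrajectoryModel":
        """Fit by maximum likelihood; deterministic given data and settings.

        ``groups`` optionally maps covariate names to lists of dummy
        columns for joint Wald tests of multi-level covariates.
        """
        if len(baseline) < 2:
            raise ValueError("need at least 2 patients")
        if self.measure is not None:
            measurements = measurements[
                measurements["measure"] == Measure(self.measure).value]
        spec = self._spec()
        compiled = compile_cohort(measurements, baseline, spec)
        layout = _FitLayout(spec, compiled.long_names)

        if self.init is not None:
            b_long0 = np.concatenate([
                self.init.beta, [self.init.delta],
                np.zeros(self.time_degree - 1), self.init.theta])
            psi0 = layout.pack(self.init, b_long0)
        else:
            psi0 = _initial_psi(compiled, layout)

        cache: dict[bytes, float] = {}
        n_eval = 0

        def nll(psi: np.ndarray) -> float:
            nonlocal n_eval
            n_eval += 1
            params, b_long = layout.unpack(psi)
            val = -_loglik_compiled(params, compiled, n_nodes=self.n_quad,
                                    b_long=b_long)
            if not np.isfinite(val):
                val = 1e12
            key = psi.tobytes()
            cache[key] = val
            if len(cache) > 400:
                cache.pop(next(iter(cache)))
            return val

        trace: list[float] = []

        def callback(xk):
            trace.append(-cache.get(xk.tobytes(), nll(xk)))

        opts = {"maxiter": self.max_iter, "ftol": self.ftol,
                "gtol": self.gtol, "maxcor": 25}
        res = optimize.minimize(nll, psi0, method="L-BFGS-B", jac="2-point",
                                callback=callback, options=opts)
        if not res.success:  # one restart with fresh curvature memory
            res2 = optimize.minimize(nll, res.x, method="L-BFGS-B",
                                     jac="2-point", callback=callback,
                                     options=opts)
            if res2.fun <= res.fun:
                res = res2
        psi_hat = res.x
        params, b_long = layout.unpack(psi_hat)
        converged = bool(res.success)
        if not converged:
            warnings.warn(f"optimizer did not converge: {res.message}",
                          RuntimeWarning, stacklevel=2)

        nat = layout.natural(psi_hat)
        se = np.full(layout.n, np.nan)
        cov = np.full((layout.n, layout.n), np.nan)
        if self.compute_se:
            for rel_step in (1e-4, 1e-3):
                hess = _numeric_hessian(nll, psi_hat, rel_step=rel_step)
                cov = pinvh(hess)
                var = np.diag(cov).copy()
                if np.all(var > 0):
                    break
            bad = var <= 0
            if bad.any():
                warnings.warn(
                    "observed information not positive definite; some SEs "
                    "undefined", RuntimeWarning, stacklevel=2)
                var[bad] = np.nan
            se = np.sqrt(var) * layout.jacobian_diag(psi_hat)

        self.layout_ = layout
        self.compiled_ = compiled
        self.params_ = params
        self.b_long_ = b_long
        self.loglik_ = float(-res.fun)
        self.converged_ = converged
        self.n_iter_ = int(res.nit)
        self.result_ = JointFitResult(
            params=params, b_long=b_long, names=list(layout.names),
            estimates=nat, se=se, cov_transformed=cov,
            loglik=self.loglik_, converged=converged, n_iter=int(res.nit),
            n_evaluations=n_eval, trace=np.asarray(trace), spec=spec,
            n_patients=compiled.n_patients,
            n_measurements=int(compiled.tau.size),
            message=str(res.message), groups=groups or {},
        )
        if self.compute_se and self.interactions:
            self.result_.wald = wald_interaction_tests(self.result_)
        self.se_ = se
        return self

    # -- post-fit conveniences -----------------------------------------
    @property
    def annual_decline_(self) -> float:
        return -self.params_.delta

    def log_likelihood(self, params: Optional[JointModelParams] = None) -> float:
        params = params or self.params_
        return _loglik_compiled(params, self.compiled_, n_nodes=self.n_quad,
                                use_cache=False)

    def predict_mean(self, days: np.ndarray,
                     baseline: Optional[pd.DataFrame] = None) -> np.ndarray:
        """Marginal mean % predicted at the given follow-up days, averaged
        over the fitted cohort's covariate rows (or the given table)."""
        traj = estimate_mean_trajectory(
            self.result_, baseline if baseline is not None else None,
            horizon_days=float(np.max(days)), days=np.asarray(days, dtype=float))
        return traj.overall


# ---------------------------------------------------------------------------
# Wald tests
# ---------------------------------------------------------------------------

def _joint_wald(result: JointFitResult, labels: list[str]) -> tuple[float, int, float]:
    idx = [result.names.index(lab) for lab in labels]
    est = result.estimates[idx]
    sub = result.cov_transformed[np.ix_(idx, idx)]
    stat = float(est @ np.linalg.solve(sub, est))
    df = len(idx)
    return stat, df, float(chi2.sf(stat, df))


def wald_interaction_tests(result: JointFitResult,
                           groups: Optional[dict] = None) -> pd.DataFrame:
    """Wald tests of each covariate-by-time interaction and main effect.

    Main-effect p-values are reported only where the interaction is not
    significant at the 5% level (the interaction row then describes the
    covariate); p-values are unadjusted for multiplicity.
    """
    groups = groups or result.groups or {}
    spec = result.spec
    # default: each interaction column is its own group
    if not groups:
        groups = {c: [c] for c in spec.interactions}
    rows = []
    for cov_name, cols in groups.items():
        int_cols = [f"theta:{c}" for c in cols if c in spec.interactions]
        main_cols = [f"beta:{c}" for c in cols if c in spec.covariates]
        if not int_cols and not main_cols:
            raise KeyError(f"covariate {cov_name!r} not in the fitted model")
        int_p = main_p = np.nan
        int_stat = main_stat = np.nan
        if int_cols:
            int_stat, _, int_p = _joint_wald(result, int_cols)
        if main_cols:
            main_stat, _, main_p = _joint_wald(result, main_cols)
        rows.append({
            "covariate": cov_name,
            "interaction_stat": int_stat,
            "interaction_p": int_p,
            "main_stat": main_stat,
            "main_p": (main_p if (np.isnan(int_p) or int_p >= 0.05)
                       else np.nan),
            "main_p_unconditional": main_p,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def estimate_mean_trajectory(
    result: JointFitResult,
    baseline: Optional[pd.DataFrame] = None,
    subgroup: Optional[str] = None,
    horizon_days: float = 4 * 365.25,
    days: Optional[np.ndarray] = None,
) -> TrajectoryEstimate:
    """Estimated mean % predicted at each day of follow-up.

    The marginal mean at day ``t`` averages the fitted fixed-effects mean
    over the observed covariate rows; subgroup curves restrict the average
    to the subgroup's members (``subgroup`` names a column of ``baseline``).
    Intercepts are the day-0 values; slopes are per year (exact for the
    linear-in-time model, otherwise the least-squares line through the
    curve).
    """
    spec = result.spec
    if days is None:
        days = np.arange(0.0, np.floor(horizon_days) + 1.0)
    tau = days / DAYS_PER_YEAR
    need_cov = bool(spec.covariates)
    if (need_cov or subgroup) and baseline is None:
        raise ValueError("covariate model needs the baseline table")

    def curve_for(rows: Optional[pd.DataFrame]) -> tuple[np.ndarray, float, float]:
        if spec.covariates:
            xm = rows[list(spec.covariates)].to_numpy(dtype=float).mean(axis=0)
            xi = rows[list(spec.interactions)].to_numpy(dtype=float).mean(axis=0) \
                if spec.interactions else np.zeros(0)
        else:
            xm = np.zeros(0)
            xi = np.zeros(0)
        p = result.params
        intercept = float(p.beta[0] + xm @ p.beta[1:])
        slope = float(p.delta + xi @ p.theta)
        curve = intercept + slope * tau
        layout_poly = [n for n in result.names if n.startswith("time^")]
        for k, name in enumerate(layout_poly, start=2):
            curve = curve + result.estimate_for(name) * tau ** k
        if layout_poly:
            slope = float(np.polyfit(tau, curve, 1)[0])
        return curve, intercept, slope

    overall_rows = baseline if baseline is not None else None
    overall, ic0, sl0 = curve_for(overall_rows)
    groups_out, intercepts, slopes = {}, {"overall": ic0}, {"overall": sl0}
    if subgroup is not None:
        for label, rows in baseline.groupby(subgroup):
            if len(rows) == 0:
                continue
            c, ic, sl = curve_for(rows)
            key = str(label)
            groups_out[key] = c
            intercepts[key] = ic
            slopes[key] = sl
        if not groups_out:
            raise ValueError(f"no non-empty levels of subgroup {subgroup!r}")
    return TrajectoryEstimate(days=days, overall=overall, groups=groups_out,
                              intercepts=intercepts, slopes=slopes)


# ---------------------------------------------------------------------------
# baseline-value-as-predictor variant
# ---------------------------------------------------------------------------

class BaselineValueTrajectoryModel(JointTrajectoryModel):
    """Modified joint model with the enrolment measurement as a predictor.

    The enrolment measurement (closest to day 0 within ``window_days``,
    pre-enrolment preferred on ties) is removed from the outcomes, centred
    at ``centre`` and entered as a main effect and a by-time interaction,
    so the fitted annual slope is linear in the enrolment value:
    ``slope(b) = delta + theta * (b - centre)``.  Patients without an
    enrolment measurement are excluded (count in ``n_excluded_``).
    """

    def __init__(self, centre: float = 60.0, window_days: float = 30.0,
                 in_event_models: bool = True, **kwargs):
        kwargs.setdefault("covariates", ("baseline_centred",))
        kwargs.setdefault("interactions", ("baseline_centred",))
        if in_event_models:
            kwargs.setdefault("visit_covariates", ("baseline_centred",))
            kwargs.setdefault("hazard_covariates", ("baseline_centred",))
        super().__init__(**kwargs)
        self.centre = centre
        self.window_days = window_days
        self.in_event_models = in_event_models

    def fit(self, measurements: pd.DataFrame, baseline: pd.DataFrame,
            groups: Optional[dict] = None) -> "BaselineValueTrajectoryModel":
        m = measurements
        if self.measure is not None:
            m = m[m["measure"] == Measure(self.measure).value]
        base_vals = {}
        base_rowid = {}
        for pid, grp in m.groupby("patient_id"):
            win = grp[(grp["t_days"] >= -self.window_days)
                      & (grp["t_days"] <= self.window_days)]
            if len(win) == 0:
                continue
            t = win["t_days"].to_numpy(dtype=float)
            best = win.iloc[np.lexsort((t, np.abs(t)))[0]]  # |t| first, ties -> earlier
            base_vals[pid] = float(best["value_pct_pred"])
            base_rowid[pid] = best.name
        keep = baseline["patient_id"].isin(base_vals)
        self.n_excluded_ = int((~keep).sum())
        baseline = baseline[keep].copy()
        baseline["baseline_value"] = baseline["patient_id"].map(base_vals)
        baseline["baseline_centred"] = baseline["baseline_value"] - self.centre
        outcomes = m[(m["t_days"] > 0)
                     & ~m.index.isin(base_rowid.values())
                     & m["patient_id"].isin(base_vals)]
        super().fit(outcomes, baseline, groups=groups)
        return self

    def slope_at(self, b: float) -> float:
        """Fitted annual slope at enrolment value ``b`` (% predicted/yr)."""
        return float(self.params_.delta
                     + self.params_.theta[0] * (b - self.centre))

    def annual_decline_at(self, b: float) -> float:
        return -self.slope_at(b)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_joint_model(measurements, baseline, spec: ModelSpec | None = None,
                    init: Optional[JointModelParams] = None,
                    n_quad: int = 9, measure: Optional[str] = None,
                    compute_se: bool = True, max_iter: int = 300,
                    groups: Optional[dict] = None) -> JointFitResult:
    """Fit the joint model and return the :class:`JointFitResult`."""
    spec = spec or ModelSpec()
    est = JointTrajectoryModel(
        covariates=spec.covariates, interactions=spec.interactions,
        visit_covariates=spec.visit_covariates,
        hazard_covariates=spec.hazard_covariates,
        visit_knots=spec.visit_knots, hazard_knots=spec.hazard_knots,
        time_degree=spec.time_degree, n_quad=n_quad, measure=measure,
        compute_se=compute_se, init=init, max_iter=max_iter,
    )
    est.fit(measurements, baseline, groups=groups)
    return est.result_


def fit_baseline_value_model(measurements, baseline, centre: float = 60.0,
                             window_days: float = 30.0, n_quad: int = 9,
                             measure: Optional[str] = None,
                             compute_se: bool = True) -> BaselineValueTrajectoryModel:
    """Fit the modified model with the enrolment value as predictor."""
    est = BaselineValueTrajectoryModel(
        centre=centre, window_days=window_days, n_quad=n_quad,
        measure=measure, compute_se=compute_se,
    )
    est.fit(measurements, baseline)
    return est
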