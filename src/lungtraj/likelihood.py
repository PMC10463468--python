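"""Joint likelihood of the three-part model.

Each patient contributes

``log integral integral  L_visit(u) * L_long(u, v) * L_event(u, v)
dPhi(u; sigma2_u) dPhi(v; sigma2_v)``

where the visit process is an inhomogeneous Poisson process with
piecewise-constant baseline intensity, the longitudinal values are Gaussian
around a linear-in-time mean shifted by ``gamma1*u + v``, and the terminal
event is piecewise-exponential with log-hazard shifted by
``gamma2*u + gamma3*v``.  The two-dimensional integral is evaluated by
adaptive Gauss-Hermite quadrature: the integrand is log-concave in (u, v),
so its mode and curvature are found by a damped Newton iteration
(vectorized across patients) and the quadrature grid is recentred and
rescaled per patient.

All time quantities are converted to years at compilation; baseline pieces
are rates per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import logsumexp

from .cohort import DAYS_PER_YEAR
from .params import JointModelParams

__all__ = [
    "ModelSpec",
    "CompiledCohort",
    "compile_cohort",
    "joint_log_likelihood",
    "mc_loglik_oracle",
    "MCLogLik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_EXP_CAP = 700.0  # exp() argument cap; keeps extreme optimizer trials finite


def _safe_exp(x):
    return np.exp(np.minimum(x, _EXP_CAP))


@dataclass(frozen=True)
class ModelSpec:
    """Names the covariates, interactions and knot grids of a fit.

    Covariates are numeric columns of the per-patient table (categorical
    covariates must be dummy-coded first, see
    :func:`lungtraj.model.encode_covariates`).  ``covariates`` enter the
    longitudinal mean, ``interactions`` (a subset) additionally interact
    with time, ``visit_covariates``/``hazard_covariates`` enter the
    respective log-linear predictors.  ``time_degree`` > 1 adds polynomial
    time terms to the longitudinal mean.  Knots are in years from 0.
    """

    covariates: tuple[str, ...] = ()
    interactions: tuple[str, ...] = ()
    visit_covariates: tuple[str, ...] = ()
    hazard_covariates: tuple[str, ...] = ()
    visit_knots: tuple[float, ...] = (0.0,)
    hazard_knots: tuple[float, ...] = (0.0,)
    time_degree: int = 1

    def __post_init__(self):
        missing = set(self.interactions) - set(self.covariates)
        if missing:
            raise ValueError(
                f"interactions must be a subset of covariates; extra: {sorted(missing)}")
        if self.time_degree < 1:
            raise ValueError("time_degree must be >= 1")

    def template_params(self) -> JointModelParams:
        """A zero-initialized parameter object with this spec's layout."""
        return JointModelParams(
            log_lambda0=np.zeros(len(self.visit_knots)),
            alpha=np.zeros(len(self.visit_covariates)),
            sigma2_u=0.1,
            beta=np.zeros(1 + len(self.covariates)),
            delta=0.0,
            theta=np.zeros(len(self.interactions)),
            gamma1=0.0, sigma2_v=1.0, sigma2_e=1.0,
            log_h0=np.zeros(len(self.hazard_knots)),
            phi=np.zeros(len(self.hazard_covariates)),
            gamma2=0.0, gamma3=0.0,
            visit_knots=np.asarray(self.visit_knots),
            hazard_knots=np.asarray(self.hazard_knots),
        )


def _piece_exposure(knots: np.ndarray, t: np.ndarray) -> np.ndarray:
    """(n, K) time spent in each piece before t (years)."""
    upper = np.append(knots[1:], np.inf)
    return np.clip(t[:, None] - knots[None, :], 0.0,
                   (upper - knots)[None, :])


def _piece_index(knots: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.clip(np.searchsorted(knots, t, side="right") - 1, 0, len(knots) - 1)


@dataclass
class CompiledCohort:
    """Cohort reduced to the per-patient arrays the likelihood needs."""

    patient_ids: np.ndarray
    # visit-level
    pidx: np.ndarray          # visit -> patient index
    tau: np.ndarray           # visit times, years
    y: np.ndarray
    X_long: np.ndarray        # (n_visits, p_long) fixed-effects design
    # patient-level
    n_visits: np.ndarray
    T: np.ndarray             # follow-up years
    d: np.ndarray             # terminal-event indicator (0/1)
    X_vis: np.ndarray
    X_haz: np.ndarray
    E_vis: np.ndarray         # exposure per visit piece
    C_vis: np.ndarray         # visit count per piece
    E_haz: np.ndarray
    idx_haz: np.ndarray       # hazard piece containing T
    spec: ModelSpec = field(default=ModelSpec())
    long_names: tuple = ()
    _mode_cache: Optional[np.ndarray] = None

    @property
    def n_patients(self) -> int:
        return self.T.size


def compile_cohort(measurements, baseline, spec: ModelSpec | None = None,
                   min_time_days: float = 0.0) -> CompiledCohort:
    """Build the fitting arrays from the long and per-patient tables.

    ``baseline`` must carry ``patient_id``, ``censor_days``, an ``event``
    boolean with ``t_event_days``, and any covariate columns the spec
    names.  Measurements earlier than ``min_time_days`` (default: the
    enrolment day) are excluded from the visit process and the outcomes.
    """
    spec = spec or ModelSpec()
    baseline = baseline.reset_index(drop=True)
    pid_order = baseline["patient_id"].astype(str).to_numpy()
    pid_to_idx = {p: i for i, p in enumerate(pid_order)}
    if len(pid_to_idx) != len(pid_order):
        raise ValueError("duplicate patient_id in baseline table")

    m = measurements[measurements["t_days"] >= min_time_days].copy()
    unknown = set(m["patient_id"].astype(str)) - set(pid_order)
    if unknown:
        raise ValueError(f"measurements for patients absent from baseline: "
                         f"{sorted(unknown)[:5]}...")
    pidx = m["patient_id"].astype(str).map(pid_to_idx).to_numpy(dtype=int)
    tau = m["t_days"].to_numpy(dtype=float) / DAYS_PER_YEAR
    y = m["value_pct_pred"].to_numpy(dtype=float)

    n_pat = len(pid_order)
    event = baseline["event"].to_numpy(dtype=bool) if "event" in baseline else \
        np.zeros(n_pat, dtype=bool)
    censor = baseline["censor_days"].to_numpy(dtype=float) / DAYS_PER_YEAR
    t_event = (baseline["t_event_days"].to_numpy(dtype=float) / DAYS_PER_YEAR
               if "t_event_days" in baseline else np.full(n_pat, np.nan))
    T = np.where(event, t_event, censor)
    if np.any(~np.isfinite(T)) or np.any(T <= 0):
        raise ValueError("every patient needs a positive event or censor time")
    if np.any(tau > T[pidx] + 1e-9):
        raise ValueError("measurement after the patient's follow-up end")

    def _design(cols: Sequence[str]) -> np.ndarray:
        if not cols:
            return np.zeros((n_pat, 0))
        arr = baseline[list(cols)].to_numpy(dtype=float)
        if np.any(~np.isfinite(arr)):
            raise ValueError("missing values in model covariates; impute first")
        return arr

    x_main = _design(spec.covariates)
    X_vis = _design(spec.visit_covariates)
    X_haz = _design(spec.hazard_covariates)
    x_int = _design(spec.interactions)

    # longitudinal design: [1, x_main, tau, tau^2.., x_int * tau]
    cols = [np.ones(len(tau))]
    names = ["beta[0]"]
    for j, c in enumerate(spec.covariates):
        cols.append(x_main[pidx, j])
        names.append(f"beta:{c}")
    cols.append(tau)
    names.append("delta")
    for k in range(2, spec.time_degree + 1):
        cols.append(tau ** k)
        names.append(f"time^{k}")
    for j, c in enumerate(spec.interactions):
        cols.append(x_int[pidx, j] * tau)
        names.append(f"theta:{c}")
    X_long = np.column_stack(cols) if len(tau) else np.zeros((0, len(cols)))

    vk = np.asarray(spec.visit_knots, dtype=float)
    hk = np.asarray(spec.hazard_knots, dtype=float)
    E_vis = _piece_exposure(vk, T)
    E_haz = _piece_exposure(hk, T)
    C_vis = np.zeros((n_pat, len(vk)))
    np.add.at(C_vis, (pidx, _piece_index(vk, tau)), 1.0)
    idx_haz = _piece_index(hk, T)
    n_visits = np.bincount(pidx, minlength=n_pat).astype(float)

    return CompiledCohort(
        patient_ids=pid_order, pidx=pidx, tau=tau, y=y, X_long=X_long,
        n_visits=n_visits, T=T, d=event.astype(float), X_vis=X_vis,
        X_haz=X_haz, E_vis=E_vis, C_vis=C_vis, E_haz=E_haz, idx_haz=idx_haz,
        spec=spec, long_names=tuple(names),
    )


# ---------------------------------------------------------------------------
# per-patient summaries and the conditional log-likelihood
# ---------------------------------------------------------------------------

def _long_coef(params: JointModelParams, spec: ModelSpec) -> np.ndarray:
    """Fixed-effects coefficient vector aligned with the X_long columns.

    Polynomial time terms beyond degree 1 are not carried by
    ``JointModelParams`` (the fitter stores them separately), so this
    helper only serves the degree-1 layout.
    """
    if spec.time_degree != 1:
        raise ValueError("use the fitter's own coefficient vector for degree > 1")
    return np.concatenate([params.beta, [params.delta], params.theta])


@dataclass
class _Summaries:
    """Per-patient scalars entering the conditional log-likelihood."""

    K: np.ndarray    # (u,v)-free terms
    n: np.ndarray
    a: np.ndarray    # exp(alpha.x) * Lambda0(T)
    Sr: np.ndarray   # sum of fixed-effect residuals
    c: np.ndarray    # exp(phi.x) * H0(T)
    d: np.ndarray
    sigma2_e: float


def _summaries(params: JointModelParams, compiled: CompiledCohort,
               b_long: np.ndarray | None = None) -> _Summaries:
    spec = compiled.spec
    if b_long is None:
        b_long = _long_coef(params, spec)
    lam = np.exp(params.log_lambda0)
    h = np.exp(params.log_h0)
    eta_vis = compiled.X_vis @ params.alpha
    eta_haz = compiled.X_haz @ params.phi
    a = np.exp(eta_vis) * (compiled.E_vis @ lam)
    c = np.exp(eta_haz) * (compiled.E_haz @ h)
    sumloglam = compiled.C_vis @ params.log_lambda0
    log_hT = params.log_h0[compiled.idx_haz]
    r = compiled.y - compiled.X_long @ b_long
    n_pat = compiled.n_patients
    Sr = np.bincount(compiled.pidx, weights=r, minlength=n_pat)
    Sr2 = np.bincount(compiled.pidx, weights=r * r, minlength=n_pat)
    s2e = params.sigma2_e
    K = (sumloglam + compiled.n_visits * eta_vis
         + compiled.d * (log_hT + eta_haz)
         - 0.5 * compiled.n_visits * (_LOG_2PI + np.log(s2e))
         - Sr2 / (2.0 * s2e))
    return _Summaries(K=K, n=compiled.n_visits, a=a, Sr=Sr, c=c,
                      d=compiled.d, sigma2_e=s2e)


def _conditional_loglik(s: _Summaries, params: JointModelParams,
                        u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """log of visit x longitudinal x terminal likelihood given (u, v).

    ``u``/``v`` broadcast against the patient axis (first axis of ``s``
    fields after expansion by the caller).
    """
    g1, g2, g3 = params.gamma1, params.gamma2, params.gamma3
    mshift = g1 * u + v
    expand = (...,) + (None,) * (u.ndim - 1)
    K, n, a, Sr, c, d = (arr[expand] for arr in (s.K, s.n, s.a, s.Sr, s.c, s.d))
    return (K + n * u - a * _safe_exp(u)
            + (2.0 * mshift * Sr - n * mshift * mshift) / (2.0 * s.sigma2_e)
            + d * (g2 * u + g3 * v) - c * _safe_exp(g2 * u + g3 * v))


def _newton_modes(s: _Summaries, params: JointModelParams,
                  start: Optional[np.ndarray] = None,
                  tol: float = 1e-10, max_iter: int = 100):
    """Joint mode and curvature of the (u, v) log-integrand per patient.

    The integrand (conditional likelihood times the two normal priors) is
    strictly log-concave, so damped Newton from any start converges to the
    unique maximum.  Returns ``(modes (n,2), (huu, huv, hvv))`` of the
    log-integrand Hessian at the mode.
    """
    g1, g2, g3 = params.gamma1, params.gamma2, params.gamma3
    s2u, s2v, s2e = params.sigma2_u, params.sigma2_v, s.sigma2_e
    n_pat = s.n.size
    if start is None:
        uv = np.zeros((n_pat, 2))
    else:
        # warm starts from a previous parameter value speed convergence, but
        # a cached mode from a catastrophic trial point must not trap the
        # damped iteration far from the optimum
        uv = np.where(np.isfinite(start) & (np.abs(start) < 50.0), start, 0.0)
    u, v = uv[:, 0], uv[:, 1]

    def hessian(u, v):
        E1 = np.minimum(s.a * _safe_exp(u), 1e150)
        E2 = np.minimum(s.c * _safe_exp(g2 * u + g3 * v), 1e150)
        huu = np.minimum(-E1 - s.n * g1 * g1 / s2e - g2 * g2 * E2 - 1.0 / s2u,
                         -1e-12)
        huv = -s.n * g1 / s2e - g2 * g3 * E2
        hvv = np.minimum(-s.n / s2e - g3 * g3 * E2 - 1.0 / s2v, -1e-12)
        return E1, E2, huu, huv, hvv

    for _ in range(max_iter):
        E1, E2, huu, huv, hvv = hessian(u, v)
        m = g1 * u + v
        resid = (s.Sr - s.n * m) / s2e
        gu = s.n - E1 + g1 * resid + s.d * g2 - g2 * E2 - u / s2u
        gv = resid + s.d * g3 - g3 * E2 - v / s2v
        det = np.maximum(huu * hvv - huv * huv, 1e-300)
        du = -(hvv * gu - huv * gv) / det
        dv = -(huu * gv - huv * gu) / det
        step = np.maximum(np.abs(du), np.abs(dv))
        damp = np.minimum(1.0, 3.0 / np.maximum(step, 1e-300))
        u += damp * du
        v += damp * dv
        if step.max() < tol:
            break
    _, _, huu, huv, hvv = hessian(u, v)
    return uv, (huu, huv, hvv)


def _loglik_compiled(params: JointModelParams, compiled: CompiledCohort,
                     n_nodes: int = 9, b_long: np.ndarray | None = None,
                     use_cache: bool = True) -> float:
    """Total log-likelihood by adaptive Gauss-Hermite quadrature."""
    if n_nodes < 1:
        raise ValueError("quadrature needs at least one node per dimension")
    if params.sigma2_u < 0 or params.sigma2_v < 0 or params.sigma2_e <= 0:
        raise ValueError("variance parameters out of domain")
    s = _summaries(params, compiled, b_long=b_long)
    s2u, s2v = params.sigma2_u, params.sigma2_v

    # degenerate (point-mass) random effects: no integration over that dim
    if s2u == 0.0 and s2v == 0.0:
        z = np.zeros(compiled.n_patients)
        return float(np.sum(_conditional_loglik(s, params, z, z)))
    if s2u == 0.0 or s2v == 0.0:
        return _loglik_1d(s, params, n_nodes)

    start = compiled._mode_cache if use_cache else None
    if start is not None and start.shape[0] != compiled.n_patients:
        start = None
    modes, (huu, huv, hvv) = _newton_modes(s, params, start=start)
    if use_cache:
        compiled._mode_cache = modes.copy()

    det = np.maximum(huu * hvv - huv * huv, 1e-300)  # H negative definite
    # covariance of the Laplace approximation = (-H)^{-1}
    cuu = np.maximum(-hvv / det, 1e-300)
    cuv = huv / det
    cvv = -huu / det
    l11 = np.sqrt(cuu)
    l21 = cuv / l11
    l22 = np.sqrt(np.maximum(cvv - l21 * l21, 1e-300))

    z, w = hermgauss(n_nodes)
    z1 = np.repeat(z, n_nodes)
    z2 = np.tile(z, n_nodes)
    const = (np.log(np.repeat(w, n_nodes)) + np.log(np.tile(w, n_nodes))
             + z1 * z1 + z2 * z2)

    u_pts = modes[:, 0][:, None] + np.sqrt(2.0) * l11[:, None] * z1[None, :]
    v_pts = (modes[:, 1][:, None]
             + np.sqrt(2.0) * (l21[:, None] * z1[None, :]
                               + l22[:, None] * z2[None, :]))
    g = _conditional_loglik(s, params, u_pts, v_pts)
    g -= 0.5 * (_LOG_2PI + np.log(s2u)) + u_pts * u_pts / (2.0 * s2u)
    g += -0.5 * (_LOG_2PI + np.log(s2v)) - v_pts * v_pts / (2.0 * s2v)
    ll = (np.log(2.0) + np.log(l11) + np.log(l22)
          + logsumexp(g + const[None, :], axis=1))
    total = float(np.sum(ll))
    return total if np.isfinite(total) else float("-inf")


def _loglik_1d(s: _Summaries, params: JointModelParams, n_nodes: int) -> float:
    """One random-effect dimension collapsed to a point mass."""
    over_u = params.sigma2_v == 0.0
    sigma2 = params.sigma2_u if over_u else params.sigma2_v
    n_pat = s.n.size
    x = np.zeros(n_pat)
    g1, g2, g3 = params.gamma1, params.gamma2, params.gamma3
    s2e = s.sigma2_e

    def grad_hess(x):
        u = x if over_u else np.zeros_like(x)
        v = x if not over_u else np.zeros_like(x)
        E1 = np.minimum(s.a * _safe_exp(u), 1e150)
        E2 = np.minimum(s.c * _safe_exp(g2 * u + g3 * v), 1e150)
        m = g1 * u + v
        resid = (s.Sr - s.n * m) / s2e
        if over_u:
            grad = (s.n - E1 + g1 * resid + s.d * g2 - g2 * E2 - x / sigma2)
            hess = -E1 - s.n * g1 * g1 / s2e - g2 * g2 * E2 - 1.0 / sigma2
        else:
            grad = resid + s.d * g3 - g3 * E2 - x / sigma2
            hess = -s.n / s2e - g3 * g3 * E2 - 1.0 / sigma2
        return grad, np.minimum(hess, -1e-12)

    for _ in range(100):
        grad, hess = grad_hess(x)
        dx = -grad / hess
        x += np.clip(dx, -3.0, 3.0)
        if np.abs(dx).max() < 1e-10:
            break
    _, hess = grad_hess(x)
    sd = np.sqrt(-1.0 / hess)

    z, w = hermgauss(n_nodes)
    pts = x[:, None] + np.sqrt(2.0) * sd[:, None] * z[None, :]
    zero = np.zeros_like(pts)
    g = (_conditional_loglik(s, params, pts, zero) if over_u
         else _conditional_loglik(s, params, zero, pts))
    g -= 0.5 * (_LOG_2PI + np.log(sigma2)) + pts * pts / (2.0 * sigma2)
    const = np.log(w) + z * z
    ll = 0.5 * np.log(2.0) + np.log(sd) + logsumexp(g + const[None, :], axis=1)
    return float(np.sum(ll))


def joint_log_likelihood(
    params: JointModelParams,
    measurements,
    baseline,
    spec: ModelSpec | None = None,
    n_nodes: int = 9,
) -> float:
    """Joint log-likelihood of a cohort at the given parameters.

    Convenience wrapper around the compiled fast path; the fitter compiles
    once and reuses the arrays.
    """
    if spec is None:
        spec = ModelSpec(visit_knots=tuple(params.visit_knots),
                         hazard_knots=tuple(params.hazard_knots))
    compiled = compile_cohort(measurements, baseline, spec)
    return _loglik_compiled(params, compiled, n_nodes=n_nodes, use_cache=False)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCLogLik:
    value: float
    se: float
    n_draws: int


def mc_loglik_oracle(
    params: JointModelParams,
    measurements,
    baseline,
    spec: ModelSpec | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
) -> MCLogLik:
    """Plain Monte-Carlo estimate of the integrated log-likelihood.

    Written as an explicit per-patient loop over prior draws of (u, v),
    deliberately independent of the vectorized quadrature path; used as a
    cross-check oracle and never in fitting.  The reported standard error
    is the delta-method SE of the summed log-likelihood.
    """
    if spec is None:
        spec = ModelSpec(visit_knots=tuple(params.visit_knots),
                         hazard_knots=tuple(params.hazard_knots))
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, np.sqrt(params.sigma2_u), n_draws)
    v = rng.normal(0.0, np.sqrt(params.sigma2_v), n_draws)

    lam = np.exp(params.log_lambda0)
    h0 = np.exp(params.log_h0)
    vk = np.asarray(spec.visit_knots)
    hk = np.asarray(spec.hazard_knots)
    b_long = _long_coef(params, spec)

    def cum(knots, rates, t):
        upper = np.append(knots[1:], np.inf)
        return float(np.clip(t - knots, 0, upper - knots) @ rates)

    total, var = 0.0, 0.0
    baseline = baseline.reset_index(drop=True)
    for i, row in baseline.iterrows():
        pid = row["patient_id"]
        mrows = measurements[(measurements["patient_id"] == pid)
                             & (measurements["t_days"] >= 0)]
        tau = mrows["t_days"].to_numpy(dtype=float) / DAYS_PER_YEAR
        yv = mrows["value_pct_pred"].to_numpy(dtype=float)
        event = bool(row.get("event", False))
        T = (float(row["t_event_days"]) if event else float(row["censor_days"])) \
            / DAYS_PER_YEAR
        x_main = (np.array([row[c] for c in spec.covariates], dtype=float)
                  if spec.covariates else np.zeros(0))
        x_int = (np.array([row[c] for c in spec.interactions], dtype=float)
                 if spec.interactions else np.zeros(0))
        x_vis = (np.array([row[c] for c in spec.visit_covariates], dtype=float)
                 if spec.visit_covariates else np.zeros(0))
        x_haz = (np.array([row[c] for c in spec.hazard_covariates], dtype=float)
                 if spec.hazard_covariates else np.zeros(0))

        eta_vis = float(x_vis @ params.alpha)
        eta_haz = float(x_haz @ params.phi)
        Lam0 = cum(vk, lam, T)
        H0 = cum(hk, h0, T)
        fixed_mean = (params.beta[0] + x_main @ params.beta[1:]
                      + (params.delta + x_int @ params.theta) * tau)

        loglam_at_visits = float(
            np.sum(params.log_lambda0[_piece_index(vk, tau)])) + len(tau) * eta_vis
        log_hT = float(params.log_h0[_piece_index(hk, np.array([T]))[0]]) + eta_haz

        mshift = params.gamma1 * u + v  # (n_draws,)
        resid = yv[None, :] - fixed_mean[None, :] - mshift[:, None]
        ll_long = (-0.5 * len(tau) * (_LOG_2PI + np.log(params.sigma2_e))
                   - np.sum(resid * resid, axis=1) / (2.0 * params.sigma2_e))
        ll_vis = (loglam_at_visits + len(tau) * u
                  - np.exp(eta_vis + u) * Lam0)
        haz_shift = params.gamma2 * u + params.gamma3 * v
        ll_ev = (event * (log_hT + haz_shift)
                 - np.exp(eta_haz + haz_shift) * H0)
        g = ll_long + ll_vis + ll_ev
        gmax = g.max()
        wts = np.exp(g - gmax)
        mean_w = wts.mean()
        total += gmax + np.log(mean_w)
        var += wts.var(ddof=1) / (n_draws * mean_w * mean_w)
    return MCLogLik(value=float(total), se=float(np.sqrt(var)), n_draws=n_draws)
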