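"""Fully-conditional-specification multiple imputation and Rubin pooling.

Missing baseline covariates are imputed variable-by-variable with chained
equations: a Bayesian-bootstrap draw of the conditional model per cycle
(the model is refit on a bootstrap resample of the observed cases, which
propagates parameter uncertainty uniformly across model types), linear
regression for continuous variables and (multinomial) logistic regression
for binary/categorical ones.  The logistic fits are L2-regularized, which
also stabilizes them under perfect separation.

Longitudinal outcomes and event times are never imputed and observed cells
are never altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

__all__ = ["ImputationSet", "fcs_impute", "pool_rubin", "PooledResult"]


@dataclass
class ImputationSet:
    """``m`` completed tables plus provenance.

    Non-missing cells are identical across all tables; ``models`` records
    the conditional-model type used per imputed variable.
    """

    tables: list
    models: dict
    seed: Optional[int]
    n_cycles: int

    @property
    def m(self) -> int:
        return len(self.tables)


def _var_kind(series: pd.Series) -> str:
    obs = series.dropna()
    if pd.api.types.is_numeric_dtype(obs) and not set(obs.unique()) <= {0, 1, True, False}:
        return "linear"
    return "logistic" if obs.nunique() <= 2 else "multinomial"


def _predictors(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """One-hot numeric design from all columns except the target."""
    cols = [c for c in df.columns if c != exclude]
    parts = []
    for c in cols:
        s = df[c]
        if pd.api.types.is_numeric_dtype(s) or s.dtype == bool:
            parts.append(s.to_numpy(dtype=float)[:, None])
        else:
            levels = sorted(pd.unique(s.dropna()))
            for lev in levels[1:]:
                parts.append((s == lev).to_numpy(dtype=float)[:, None])
    if not parts:
        return np.ones((len(df), 1))
    X = np.concatenate(parts, axis=1)
    return np.column_stack([np.ones(len(df)), X])


def _draw_linear(X_obs, y_obs, X_mis, rng) -> np.ndarray:
    idx = rng.integers(0, len(y_obs), len(y_obs))
    Xb, yb = X_obs[idx], y_obs[idx]
    beta, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
    resid = yb - Xb @ beta
    df = max(len(yb) - X_obs.shape[1], 1)
    sigma = np.sqrt(np.sum(resid ** 2) / df)
    return X_mis @ beta + rng.normal(0.0, sigma, len(X_mis))


def _draw_categorical(X_obs, y_obs, X_mis, rng) -> np.ndarray:
    idx = rng.integers(0, len(y_obs), len(y_obs))
    Xb, yb = X_obs[idx], y_obs[idx]
    if len(pd.unique(yb)) < 2:  # bootstrap lost a level: sample marginally
        return rng.choice(y_obs, size=len(X_mis))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(max_iter=200, C=1.0)
        try:
            clf.fit(Xb[:, 1:], yb)
        except Exception:
            warnings.warn("conditional logistic fit failed; falling back to a "
                          "strongly ridge-penalized fit", UserWarning,
                          stacklevel=3)
            clf = LogisticRegression(max_iter=500, C=0.01)
            clf.fit(Xb[:, 1:], yb)
    probs = clf.predict_proba(X_mis[:, 1:])
    cum = probs.cumsum(axis=1)
    draws = (rng.random((len(X_mis), 1)) < cum).argmax(axis=1)
    return clf.classes_[draws]


def fcs_impute(baseline_table: pd.DataFrame, m: int = 5, n_cycles: int = 10,
               seed: Optional[int] = None,
               variables: Optional[Sequence[str]] = None) -> ImputationSet:
    """Chained-equations multiple imputation of missing covariates.

    ``variables`` limits which columns may be imputed (default: every
    column with missing cells).  Each of the ``m`` imputations runs an
    independent chain of ``n_cycles`` sweeps from a random marginal fill.
    Reproducible under ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    df = baseline_table.copy()
    targets = [c for c in (variables or df.columns) if df[c].isna().any()]
    fully_missing = [c for c in targets if df[c].isna().all()]
    if fully_missing:
        raise ValueError(f"variables 100% missing cannot be imputed: {fully_missing}")
    if not any(df[c].notna().all() for c in df.columns):
        raise ValueError("need at least one fully observed variable")
    models = {c: _var_kind(df[c]) for c in targets}
    if not targets:
        return ImputationSet(tables=[df.copy() for _ in range(m)],
                             models={}, seed=seed, n_cycles=n_cycles)

    root = np.random.default_rng(seed)
    chains = root.spawn(m)
    tables = []
    masks = {c: df[c].isna().to_numpy() for c in targets}
    for rng in chains:
        work = df.copy()
        for c in targets:  # initial fill: random draws from the observed
            obs = work[c].dropna().to_numpy()
            work.loc[masks[c], c] = rng.choice(obs, size=masks[c].sum())
        for _ in range(n_cycles):
            for c in targets:
                mask = masks[c]
                X = _predictors(work, exclude=c)
                y_obs = df[c].to_numpy()[~mask]
                if models[c] == "linear":
                    work.loc[mask, c] = _draw_linear(
                        X[~mask], y_obs.astype(float), X[mask], rng)
                else:
                    # integer codes keep sklearn happy with bool/object labels
                    codes, classes = pd.factorize(pd.Series(y_obs))
                    draws = _draw_categorical(X[~mask], codes, X[mask], rng)
                    work.loc[mask, c] = classes[np.asarray(draws, dtype=int)]
        tables.append(work)
    return ImputationSet(tables=tables, models=models, seed=seed,
                         n_cycles=n_cycles)


# ---------------------------------------------------------------------------
# Rubin pooling
# ---------------------------------------------------------------------------

@dataclass
class PooledResult:
    """Rubin-pooled estimates over ``m`` imputation fits."""

    names: list
    estimate: np.ndarray
    se: np.ndarray
    within: np.ndarray
    between: np.ndarray
    df: np.ndarray
    m: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.names, "estimate": self.estimate,
            "se": self.se, "df": self.df,
        })


def pool_rubin(fits: Sequence) -> PooledResult:
    """Pool per-imputation fits by Rubin's rules.

    ``fits`` carry aligned ``names``/``estimates``/``se`` attributes (as
    :class:`lungtraj.model.JointFitResult` does).  Pooled variance is
    ``W + (1 + 1/m) B``; with ``m = 1`` the single fit is returned
    unchanged (infinite df).
    """
    if not fits:
        raise ValueError("no fits to pool")
    names = list(fits[0].names)
    for f in fits[1:]:
        if list(f.names) != names:
            raise ValueError("fits have mismatched parameter layouts")
    est = np.stack([np.asarray(f.estimates, dtype=float) for f in fits])
    ses = np.stack([np.asarray(f.se, dtype=float) for f in fits])
    m = len(fits)
    qbar = est.mean(axis=0)
    within = (ses ** 2).mean(axis=0)
    if m == 1:
        return PooledResult(names=names, estimate=qbar, se=ses[0],
                            within=within, between=np.zeros_like(qbar),
                            df=np.full_like(qbar, np.inf), m=1)
    between = est.var(axis=0, ddof=1)
    total = within + (1.0 + 1.0 / m) * between
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * between / within
        df = (m - 1) * (1.0 + 1.0 / r) ** 2
        df[between == 0] = np.inf
    return PooledResult(names=names, estimate=qbar, se=np.sqrt(total),
                        within=within, between=between, df=df, m=m)
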