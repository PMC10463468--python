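"""Parameter container for the three-part joint model.

The joint model links three sub-models through patient-level random effects
``u`` (a log-intensity frailty on the measurement process) and ``v`` (a
random intercept on the longitudinal values):

* visit sub-model: measurements arrive as a Poisson process with intensity
  ``lambda0(t) * exp(alpha.x + u)``, ``lambda0`` piecewise-constant;
* longitudinal sub-model: ``Y(t) = beta.x + (delta + theta.x) * t
  + gamma1*u + v (+ w*t) + eps``, time ``t`` in years;
* terminal sub-model: hazard ``h0(t) * exp(phi.x + gamma2*u + gamma3*v)``,
  ``h0`` piecewise-constant.

All baseline intensity/hazard pieces are rates per year and knots are in
years since enrolment; slopes are in % predicted per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterator

import numpy as np

__all__ = ["JointModelParams"]


def _as_float_array(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


@dataclass
class JointModelParams:
    """Full parameter vector of the three linked sub-models.

    Arrays may be empty when a sub-model has no covariates.  ``sigma2_w``
    (random-slope variance) is retained as a simulation option and is not
    estimated by the fitter.
    """

    # visit (measurement-frequency) sub-model
    log_lambda0: np.ndarray = field(default_factory=lambda: np.array([np.log(2.4)]))
    alpha: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma2_u: float = 0.5

    # longitudinal sub-model; beta[0] is the intercept
    beta: np.ndarray = field(default_factory=lambda: np.array([72.9]))
    delta: float = -2.8
    theta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gamma1: float = 0.0
    sigma2_v: float = 150.0
    sigma2_e: float = 25.0
    sigma2_w: float = 0.0

    # terminal-event sub-model
    log_h0: np.ndarray = field(default_factory=lambda: np.array([np.log(0.08)]))
    phi: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gamma2: float = 0.0
    gamma3: float = 0.0

    # knot grids (years, starting at 0) for the piecewise-constant pieces
    visit_knots: np.ndarray = field(default_factory=lambda: np.zeros(1))
    hazard_knots: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        for name in ("log_lambda0", "alpha", "beta", "theta", "log_h0", "phi",
                     "visit_knots", "hazard_knots"):
            setattr(self, name, _as_float_array(getattr(self, name)))
        for name in ("sigma2_u", "sigma2_v", "sigma2_e", "sigma2_w"):
            val = float(getattr(self, name))
            if val < 0:
                raise ValueError(f"{name} must be non-negative, got {val}")
            setattr(self, name, val)
        self.delta = float(self.delta)
        self.gamma1 = float(self.gamma1)
        self.gamma2 = float(self.gamma2)
        self.gamma3 = float(self.gamma3)
        for grid, pieces, label in (
            (self.visit_knots, self.log_lambda0, "visit"),
            (self.hazard_knots, self.log_h0, "hazard"),
        ):
            if grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
                raise ValueError(f"{label} knots must strictly increase from 0")
            if grid.size != pieces.size:
                raise ValueError(
                    f"{label} grid has {grid.size} knots but {pieces.size} pieces"
                )

    # -- flat-vector serialization ------------------------------------
    def _fields(self) -> Iterator[tuple[str, np.ndarray | float]]:
        yield "log_lambda0", self.log_lambda0
        yield "alpha", self.alpha
        yield "sigma2_u", self.sigma2_u
        yield "beta", self.beta
        yield "delta", self.delta
        yield "theta", self.theta
        yield "gamma1", self.gamma1
        yield "sigma2_v", self.sigma2_v
        yield "sigma2_w", self.sigma2_w
        yield "sigma2_e", self.sigma2_e
        yield "log_h0", self.log_h0
        yield "phi", self.phi
        yield "gamma2", self.gamma2
        yield "gamma3", self.gamma3

    def names(self) -> list[str]:
        """Flat parameter names aligned with :meth:`to_vector`."""
        out: list[str] = []
        for name, val in self._fields():
            if isinstance(val, np.ndarray):
                out.extend(f"{name}[{i}]" for i in range(val.size))
            else:
                out.append(name)
        return out

    def to_vector(self) -> np.ndarray:
        """Serialize to a flat ordered vector (natural scale)."""
        parts = []
        for _, val in self._fields():
            parts.append(np.atleast_1d(np.asarray(val, dtype=float)))
        return np.concatenate(parts) if parts else np.zeros(0)

    def with_vector(self, vec: np.ndarray) -> "JointModelParams":
        """Rebuild a params object of identical layout from a flat vector."""
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.to_vector().size:
            raise ValueError(
                f"vector has {vec.size} entries, layout expects "
                f"{self.to_vector().size}"
            )
        kwargs: dict[str, Any] = {}
        i = 0
        for name, val in self._fields():
            k = val.size if isinstance(val, np.ndarray) else 1
            chunk = vec[i:i + k]
            kwargs[name] = chunk.copy() if isinstance(val, np.ndarray) else float(chunk[0])
            i += k
        return replace(self, **kwargs)

    # -- plain-text config --------------------------------------------
    def to_dict(self) -> dict:
        out: dict[str, Any] = {}
        for name, val in self._fields():
            out[name] = val.tolist() if isinstance(val, np.ndarray) else float(val)
        out["visit_knots"] = self.visit_knots.tolist()
        out["hazard_knots"] = self.hazard_knots.tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "JointModelParams":
        return cls(**d)

    @property
    def n_params(self) -> int:
        return self.to_vector().size

    @property
    def annual_decline(self) -> float:
        """Mean decline in % predicted per year (positive = declining)."""
        return -self.delta
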