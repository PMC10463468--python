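"""Conversion of raw lung-function values to % predicted.

Reference equations (e.g. the GLI-2012 spirometry equations) are supplied
as plug-ins implementing :class:`ReferenceModel`; no coefficient tables are
bundled.  DLco predictions are corrected for haemoglobin with the Cotes
factor before the % predicted ratio is formed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import pandas as pd

__all__ = [
    "ReferenceModel",
    "ConstantReference",
    "LogLinearReference",
    "DomainError",
    "UncorrectedDLcoWarning",
    "MALE_REFERENCE_HB",
    "FEMALE_REFERENCE_HB",
    "hb_correction_factor",
    "dlco_percent_predicted",
    "fvc_percent_predicted",
]

#: sex-specific reference haemoglobin (g/dL) at which the correction is 1
MALE_REFERENCE_HB = 14.6
FEMALE_REFERENCE_HB = 13.4

# Cotes: factor = 1.7*Hb / (k_sex + Hb) with k_sex = 0.7 * reference Hb,
# so the factor is exactly 1 at the reference haemoglobin.
_COTES_CONST = {"male": 10.22, "female": 9.38}


class DomainError(ValueError):
    """Inputs fall outside the reference model's supported domain."""


class UncorrectedDLcoWarning(UserWarning):
    """DLco % predicted computed without a haemoglobin correction."""


@runtime_checkable
class ReferenceModel(Protocol):
    """A named mapping from (age, sex, height) to a predicted value.

    ``predict`` must return a strictly positive predicted FVC (L) or DLco
    (mL/min/mmHg) over its supported domain and raise :class:`DomainError`
    outside it.
    """

    name: str

    def predict(self, age: float, sex: str, height_cm: float) -> float:
        ...


@dataclass(frozen=True)
class ConstantReference:
    """Predicts the same value everywhere; a stub for tests and examples."""

    value: float
    name: str = "constant"

    def predict(self, age: float, sex: str, height_cm: float) -> float:
        if self.value <= 0:
            raise DomainError("reference prediction must be positive")
        return self.value


@dataclass(frozen=True)
class LogLinearReference:
    """Reference equation of the form
    ``predicted = exp(const + ln_height*ln(height_cm) + age*a1 + age^2*a2)``
    with sex-specific coefficient rows.

    Loadable from a coefficient CSV with columns
    ``sex,const,ln_height,age,age2[,age_min,age_max,height_min,height_max]``
    so published coefficient tables can be dropped in.
    """

    coefficients: dict  # sex -> dict of coefficients
    name: str = "log_linear"

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "LogLinearReference":
        df = pd.read_csv(path)
        required = {"sex", "const", "ln_height", "age", "age2"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"coefficient file missing columns: {sorted(missing)}")
        coefs = {}
        for row in df.itertuples(index=False):
            coefs[str(row.sex)] = {
                "const": float(row.const),
                "ln_height": float(row.ln_height),
                "age": float(row.age),
                "age2": float(row.age2),
                "age_min": float(getattr(row, "age_min", 18.0)),
                "age_max": float(getattr(row, "age_max", 95.0)),
                "height_min": float(getattr(row, "height_min", 120.0)),
                "height_max": float(getattr(row, "height_max", 220.0)),
            }
        return cls(coefficients=coefs, name=name or "log_linear")

    def predict(self, age: float, sex: str, height_cm: float) -> float:
        if sex not in self.coefficients:
            raise DomainError(f"no coefficients for sex {sex!r}")
        c = self.coefficients[sex]
        if not (c["age_min"] <= age <= c["age_max"]):
            raise DomainError(f"age {age} outside [{c['age_min']}, {c['age_max']}]")
        if not (c["height_min"] <= height_cm <= c["height_max"]):
            raise DomainError(
                f"height {height_cm} outside [{c['height_min']}, {c['height_max']}]")
        pred = math.exp(c["const"] + c["ln_height"] * math.log(height_cm)
                        + c["age"] * age + c["age2"] * age * age)
        if pred <= 0:
            raise DomainError("reference prediction must be positive")
        return pred


def hb_correction_factor(hb: float, sex: str) -> float:
    """Cotes haemoglobin correction applied to the predicted DLco.

    ``1.7*Hb / (10.22 + Hb)`` for males and ``1.7*Hb / (9.38 + Hb)`` for
    females; exactly 1 at the sex-specific reference haemoglobin (14.6 and
    13.4 g/dL) and monotone increasing in Hb.
    """
    if sex not in _COTES_CONST:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if not 3.0 < hb < 25.0:
        raise ValueError(f"haemoglobin {hb} g/dL outside plausible range (3, 25)")
    return 1.7 * hb / (_COTES_CONST[sex] + hb)


def dlco_percent_predicted(
    measured: float,
    age: float,
    sex: str,
    height_cm: float,
    hb: float | None,
    ref: ReferenceModel,
) -> float:
    """DLco % predicted with the haemoglobin-corrected denominator.

    ``100 * measured / (predicted * hb_factor)``.  A low haemoglobin gives a
    factor below 1, shrinking the predicted (denominator) value and raising
    the % predicted.  When ``hb`` is missing the uncorrected ratio is
    returned and an :class:`UncorrectedDLcoWarning` is emitted.
    """
    if measured <= 0:
        raise ValueError("measured DLco must be positive")
    predicted = ref.predict(age, sex, height_cm)
    if hb is None:
        warnings.warn(
            "haemoglobin missing: DLco % predicted left uncorrected",
            UncorrectedDLcoWarning, stacklevel=2,
        )
        return 100.0 * measured / predicted
    return 100.0 * measured / (predicted * hb_correction_factor(hb, sex))


def fvc_percent_predicted(
    measured_l: float,
    age: float,
    sex: str,
    height_cm: float,
    ref: ReferenceModel,
) -> float:
    """FVC % predicted: ``100 * measured / predicted``."""
    if measured_l <= 0:
        raise ValueError("measured FVC must be positive")
    return 100.0 * measured_l / ref.predict(age, sex, height_cm)
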