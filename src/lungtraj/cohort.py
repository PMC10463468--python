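"""Cohort data layer: typed records, delimited-table I/O and descriptive
summaries for irregular lung-function follow-up data.

Conventions used throughout the package:

* times are stored in **days since enrolment** (negative values are
  pre-enrolment measurements);
* a month is 30.4375 days and a year 365.25 days for all conversions;
* the terminal event is the composite of death, lung transplant, hospice
  entry or registry withdrawal due to worsening disease; withdrawal for any
  other reason is independent right-censoring.
"""

from __future__ import annotations

import datetime as _dt
import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

__all__ = [
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "Measure",
    "TerminalEventType",
    "TerminalEvent",
    "TerminalSubgroup",
    "MeasurementRecord",
    "PatientBaseline",
    "VisitSummary",
    "MeasureVisitSummary",
    "SchemaError",
    "CohortReadWarning",
    "DegenerateFitError",
    "DescriptiveCubic",
    "read_cohort",
    "write_cohort",
    "measurements_to_frame",
    "baselines_to_frame",
    "frame_to_measurements",
    "frame_to_baselines",
    "select_baseline_measurement",
    "assign_terminal_subgroup",
    "summarize_visit_patterns",
    "fit_descriptive_trajectory",
]


class Measure(str, enum.Enum):
    """Lung-function measure: spirometric FVC or diffusing capacity."""

    FVC = "FVC"
    DLCO = "DLCO"


class TerminalEventType(str, enum.Enum):
    DEATH = "death"
    TRANSPLANT = "transplant"
    HOSPICE = "hospice"
    WITHDRAWAL_WORSENING = "withdrawal_worsening"


class TerminalSubgroup(str, enum.Enum):
    """Time-to-terminal-event subgroups used in descriptive trajectories."""

    NO_EVENT = "no event"
    WITHIN_1Y = "<=1 year"
    Y1_TO_2 = ">1 to <=2 years"
    Y2_TO_3 = ">2 to <=3 years"
    AFTER_3Y = ">3 years"


@dataclass(frozen=True)
class TerminalEvent:
    type: TerminalEventType
    t_event: float  # days since enrolment

    def __post_init__(self):
        if self.t_event < 0:
            raise ValueError(f"terminal event time must be >= 0, got {self.t_event}")


@dataclass(frozen=True)
class MeasurementRecord:
    """One lung-function observation.

    ``t`` is days since enrolment; ``value_pct_pred`` is the % predicted
    value; ``raw_value`` optionally carries the raw measurement (L for FVC,
    mL/min/mmHg for DLco) and ``haemoglobin`` the g/dL value used for the
    DLco correction.
    """

    patient_id: str
    t: float
    measure: Measure
    value_pct_pred: float
    raw_value: Optional[float] = None
    haemoglobin: Optional[float] = None

    def __post_init__(self):
        if not self.value_pct_pred > 0:
            raise ValueError(
                f"value_pct_pred must be positive, got {self.value_pct_pred}"
            )
        if self.measure not in (Measure.FVC, Measure.DLCO):
            raise ValueError(f"unknown measure {self.measure!r}")


@dataclass(frozen=True)
class PatientBaseline:
    """Enrolment covariates and follow-up outcome for one patient.

    Missing covariates are ``None``.  ``censor_time`` is the administrative
    censoring time in days; when a terminal event is present its time must
    not exceed ``censor_time``.
    """

    patient_id: str
    age: Optional[float] = None
    sex: Optional[str] = None                  # "male" / "female"
    race_ethnicity: Optional[str] = None       # "white_non_hispanic" / "other"
    bmi: Optional[float] = None
    family_history_ild: Optional[bool] = None
    diagnostic_criteria: Optional[str] = None  # "definite"/"probable"/"possible"
    prior_diagnosis: Optional[bool] = None
    oxygen_use: Optional[str] = None           # "none"/"activity_only"/"activity_and_rest"
    antifibrotic: Optional[bool] = None
    ever_smoked: Optional[bool] = None
    osa: Optional[bool] = None
    enrolment_date: Optional[_dt.date] = None
    terminal_event: Optional[TerminalEvent] = None
    censor_time: float = float("nan")

    def __post_init__(self):
        if self.terminal_event is not None and np.isfinite(self.censor_time):
            if self.terminal_event.t_event > self.censor_time + 1e-9:
                raise ValueError(
                    f"patient {self.patient_id}: event time "
                    f"{self.terminal_event.t_event} exceeds censor time "
                    f"{self.censor_time}"
                )


@dataclass(frozen=True)
class MeasureVisitSummary:
    n_patients: int
    count_median: float
    count_q1: float
    count_q3: float
    count_max: int
    interval_months_median: float
    interval_months_q1: float
    interval_months_q3: float
    followup_months_median: float
    followup_months_q1: float
    followup_months_q3: float

    def __post_init__(self):
        if not (self.count_q1 <= self.count_median <= self.count_q3):
            raise ValueError("count quantiles must be ordered Q1 <= median <= Q3")


@dataclass(frozen=True)
class VisitSummary:
    """Visit-pattern summaries per measure type."""

    per_measure: dict  # Measure -> MeasureVisitSummary


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class CohortReadWarning(UserWarning):
    """A row could not be parsed and was skipped."""


class DegenerateFitError(ValueError):
    """Too few distinct days to fit the requested polynomial."""


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = [
    "patient_id", "t_days", "measure", "value_pct_pred", "raw_value", "haemoglobin",
]
BASELINE_COLUMNS = [
    "patient_id", "age", "sex", "race_ethnicity", "bmi", "family_history_ild",
    "diagnostic_criteria", "prior_diagnosis", "oxygen_use", "antifibrotic",
    "ever_smoked", "osa", "enrolment_date", "event_type", "t_event_days",
    "censor_days",
]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def _parse_optional_float(s: object) -> Optional[float]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return None
    return float(s)  # raises ValueError on junk


def _parse_optional_bool(s: object) -> Optional[bool]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return None
    key = str(s).strip().lower()
    if key not in _BOOL_MAP:
        raise ValueError(f"cannot parse boolean {s!r}")
    return _BOOL_MAP[key]


def _parse_optional_str(s: object) -> Optional[str]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return None
    return str(s)


def read_cohort(measurement_table_path, baseline_table_path):
    """Read a cohort from two delimited text tables.

    Returns ``(measurements, baselines)`` as lists of typed records.
    Rows that fail row-level validation (e.g. a non-numeric value field)
    are skipped with a :class:`CohortReadWarning` naming the row number;
    missing required columns raise :class:`SchemaError`.
    """
    mdf = pd.read_csv(measurement_table_path, dtype=str, keep_default_na=False)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in mdf.columns]
    if missing:
        raise SchemaError(f"measurement table missing columns: {missing}")
    records: list[MeasurementRecord] = []
    for i, row in enumerate(mdf.itertuples(index=False), start=2):  # 1 = header
        try:
            records.append(MeasurementRecord(
                patient_id=str(row.patient_id),
                t=float(row.t_days),
                measure=Measure(row.measure),
                value_pct_pred=float(row.value_pct_pred),
                raw_value=_parse_optional_float(row.raw_value),
                haemoglobin=_parse_optional_float(row.haemoglobin),
            ))
        except (ValueError, KeyError) as exc:
            warnings.warn(
                f"measurement table row {i}: {exc}; row skipped",
                CohortReadWarning, stacklevel=2,
            )

    bdf = pd.read_csv(baseline_table_path, dtype=str, keep_default_na=False)
    missing = [c for c in BASELINE_COLUMNS if c not in bdf.columns]
    if missing:
        raise SchemaError(f"baseline table missing columns: {missing}")
    baselines: list[PatientBaseline] = []
    for i, row in enumerate(bdf.itertuples(index=False), start=2):
        try:
            event = None
            etype = _parse_optional_str(row.event_type)
            if etype is not None:
                event = TerminalEvent(TerminalEventType(etype), float(row.t_event_days))
            date = _parse_optional_str(row.enrolment_date)
            baselines.append(PatientBaseline(
                patient_id=str(row.patient_id),
                age=_parse_optional_float(row.age),
                sex=_parse_optional_str(row.sex),
                race_ethnicity=_parse_optional_str(row.race_ethnicity),
                bmi=_parse_optional_float(row.bmi),
                family_history_ild=_parse_optional_bool(row.family_history_ild),
                diagnostic_criteria=_parse_optional_str(row.diagnostic_criteria),
                prior_diagnosis=_parse_optional_bool(row.prior_diagnosis),
                oxygen_use=_parse_optional_str(row.oxygen_use),
                antifibrotic=_parse_optional_bool(row.antifibrotic),
                ever_smoked=_parse_optional_bool(row.ever_smoked),
                osa=_parse_optional_bool(row.osa),
                enrolment_date=_dt.date.fromisoformat(date) if date else None,
                terminal_event=event,
                censor_time=float(row.censor_days),
            ))
        except (ValueError, KeyError) as exc:
            warnings.warn(
                f"baseline table row {i}: {exc}; row skipped",
                CohortReadWarning, stacklevel=2,
            )
    return records, baselines


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, float) and np.isnan(x):
        return ""
    return repr(x) if isinstance(x, float) else str(x)


def write_cohort(measurements: Iterable[MeasurementRecord],
                 baselines: Iterable[PatientBaseline],
                 measurement_table_path, baseline_table_path) -> None:
    """Companion writer to :func:`read_cohort`.

    Floats are written with ``repr`` so a read/write/read cycle reproduces
    the record values exactly.
    """
    mrows = []
    for r in measurements:
        mrows.append({
            "patient_id": r.patient_id,
            "t_days": _fmt(float(r.t)),
            "measure": r.measure.value,
            "value_pct_pred": _fmt(float(r.value_pct_pred)),
            "raw_value": _fmt(r.raw_value if r.raw_value is None else float(r.raw_value)),
            "haemoglobin": _fmt(r.haemoglobin if r.haemoglobin is None else float(r.haemoglobin)),
        })
    pd.DataFrame(mrows, columns=MEASUREMENT_COLUMNS).to_csv(
        measurement_table_path, index=False)

    brows = []
    for b in baselines:
        brows.append({
            "patient_id": b.patient_id,
            "age": _fmt(b.age if b.age is None else float(b.age)),
            "sex": _fmt(b.sex),
            "race_ethnicity": _fmt(b.race_ethnicity),
            "bmi": _fmt(b.bmi if b.bmi is None else float(b.bmi)),
            "family_history_ild": _fmt(b.family_history_ild),
            "diagnostic_criteria": _fmt(b.diagnostic_criteria),
            "prior_diagnosis": _fmt(b.prior_diagnosis),
            "oxygen_use": _fmt(b.oxygen_use),
            "antifibrotic": _fmt(b.antifibrotic),
            "ever_smoked": _fmt(b.ever_smoked),
            "osa": _fmt(b.osa),
            "enrolment_date": b.enrolment_date.isoformat() if b.enrolment_date else "",
            "event_type": b.terminal_event.type.value if b.terminal_event else "",
            "t_event_days": _fmt(
                float(b.terminal_event.t_event) if b.terminal_event else None),
            "censor_days": _fmt(float(b.censor_time)),
        })
    pd.DataFrame(brows, columns=BASELINE_COLUMNS).to_csv(
        baseline_table_path, index=False)


# ---------------------------------------------------------------------------
# record <-> DataFrame conversion (the model layer consumes DataFrames)
# ---------------------------------------------------------------------------

def measurements_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "t_days": [r.t for r in records],
        "measure": [r.measure.value for r in records],
        "value_pct_pred": [r.value_pct_pred for r in records],
    })


def baselines_to_frame(baselines: Iterable[PatientBaseline]) -> pd.DataFrame:
    rows = []
    for b in baselines:
        rows.append({
            "patient_id": b.patient_id,
            "age": b.age, "sex": b.sex, "race_ethnicity": b.race_ethnicity,
            "bmi": b.bmi, "family_history_ild": b.family_history_ild,
            "diagnostic_criteria": b.diagnostic_criteria,
            "prior_diagnosis": b.prior_diagnosis, "oxygen_use": b.oxygen_use,
            "antifibrotic": b.antifibrotic, "ever_smoked": b.ever_smoked,
            "osa": b.osa,
            "event": b.terminal_event is not None,
            "t_event_days": b.terminal_event.t_event if b.terminal_event else np.nan,
            "censor_days": b.censor_time,
        })
    return pd.DataFrame(rows)


def frame_to_measurements(df: pd.DataFrame) -> list[MeasurementRecord]:
    return [
        MeasurementRecord(str(r.patient_id), float(r.t_days), Measure(r.measure),
                          float(r.value_pct_pred))
        for r in df.itertuples(index=False)
    ]


def frame_to_baselines(df: pd.DataFrame) -> list[PatientBaseline]:
    out = []
    for r in df.itertuples(index=False):
        event = None
        if bool(getattr(r, "event", False)):
            event = TerminalEvent(
                TerminalEventType(getattr(r, "event_type", "death")),
                float(r.t_event_days),
            )
        out.append(PatientBaseline(
            patient_id=str(r.patient_id),
            terminal_event=event,
            censor_time=float(r.censor_days),
        ))
    return out


# ---------------------------------------------------------------------------
# baseline selection / subgrouping
# ---------------------------------------------------------------------------

def select_baseline_measurement(
    records: Sequence[MeasurementRecord],
    measure: Measure,
    window_days: float = 30.0,
) -> Optional[MeasurementRecord]:
    """The enrolment measurement: closest to day 0 within +/- ``window_days``.

    Equidistant pre/post-enrolment records tie-break to the earlier
    (pre-enrolment) one, so post-enrolment treatment cannot influence the
    chosen baseline.  Returns ``None`` when no record falls in the window.
    """
    pids = {r.patient_id for r in records}
    if len(pids) > 1:
        raise ValueError(f"records span multiple patients: {sorted(pids)}")
    eligible = [r for r in records
                if r.measure == measure and -window_days <= r.t <= window_days]
    if not eligible:
        return None
    return min(eligible, key=lambda r: (abs(r.t), r.t))


def assign_terminal_subgroup(patient: PatientBaseline) -> TerminalSubgroup:
    """Bucket a patient by time from enrolment to the terminal event.

    Patients without a terminal event (including withdrawals not due to
    worsening disease, which are plain censoring and therefore carry no
    ``terminal_event``) fall in the "no event" group.
    """
    ev = patient.terminal_event
    if ev is None:
        return TerminalSubgroup.NO_EVENT
    if ev.t_event < 0:
        raise ValueError("terminal event time must be non-negative")
    years = ev.t_event / DAYS_PER_YEAR
    if years <= 1:
        return TerminalSubgroup.WITHIN_1Y
    if years <= 2:
        return TerminalSubgroup.Y1_TO_2
    if years <= 3:
        return TerminalSubgroup.Y2_TO_3
    return TerminalSubgroup.AFTER_3Y


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def _quantiles(x: np.ndarray) -> tuple[float, float, float]:
    # single convention everywhere: linear interpolation (numpy default)
    return (float(np.quantile(x, 0.25)), float(np.quantile(x, 0.5)),
            float(np.quantile(x, 0.75)))


def summarize_visit_patterns(measurements) -> VisitSummary:
    """Per-measure counts, between-measurement intervals and follow-up span.

    ``measurements`` may be a list of :class:`MeasurementRecord` or the
    equivalent long-format DataFrame.  Intervals and follow-up are reported
    in months (30.4375 days).
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = measurements_to_frame(measurements)
    if len(measurements) == 0:
        raise ValueError("empty cohort: no measurements to summarize")
    per_measure = {}
    for measure, grp in measurements.groupby("measure"):
        counts, intervals, spans = [], [], []
        for _, pg in grp.groupby("patient_id"):
            t = np.sort(pg["t_days"].to_numpy(dtype=float))
            counts.append(len(t))
            spans.append((t[-1] - t[0]) / DAYS_PER_MONTH)
            if len(t) > 1:
                intervals.extend(np.diff(t) / DAYS_PER_MONTH)
        counts = np.asarray(counts)
        intervals = np.asarray(intervals) if intervals else np.array([np.nan])
        spans = np.asarray(spans)
        cq1, cmed, cq3 = _quantiles(counts)
        iq1, imed, iq3 = _quantiles(intervals)
        fq1, fmed, fq3 = _quantiles(spans)
        per_measure[Measure(measure)] = MeasureVisitSummary(
            n_patients=len(counts),
            count_median=cmed, count_q1=cq1, count_q3=cq3,
            count_max=int(counts.max()),
            interval_months_median=imed, interval_months_q1=iq1,
            interval_months_q3=iq3,
            followup_months_median=fmed, followup_months_q1=fq1,
            followup_months_q3=fq3,
        )
    return VisitSummary(per_measure=per_measure)


@dataclass(frozen=True)
class DescriptiveCubic:
    """Cubic least-squares fit through daily means.

    ``coef`` are ascending-power coefficients in days:
    ``mean(t) = c0 + c1*t + c2*t**2 + c3*t**3``.
    """

    coef: np.ndarray
    days: np.ndarray
    daily_means: np.ndarray
    fitted: np.ndarray


def fit_descriptive_trajectory(
    measurements,
    measure: Measure,
    baselines: Optional[Sequence[PatientBaseline]] = None,
    subgroup: Optional[TerminalSubgroup] = None,
    horizon_months: float = 48.0,
) -> DescriptiveCubic:
    """Cubic fit through daily means of % predicted over the horizon.

    Values observed on the same calendar day of follow-up are pooled into
    one daily mean (all values on a day weighted equally) and the cubic is
    an ordinary least-squares fit to the (day, daily mean) pairs with one
    point per day.  When ``subgroup`` is given, ``baselines`` must be
    supplied to map patients to their time-to-terminal-event group.
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = measurements_to_frame(measurements)
    df = measurements[measurements["measure"] == Measure(measure).value]
    if subgroup is not None:
        if baselines is None:
            raise ValueError("subgroup filtering requires baselines")
        keep = {b.patient_id for b in baselines
                if assign_terminal_subgroup(b) == subgroup}
        df = df[df["patient_id"].isin(keep)]
    horizon_days = horizon_months * DAYS_PER_MONTH
    day = np.rint(df["t_days"].to_numpy(dtype=float)).astype(int)
    ok = (day >= 0) & (day <= horizon_days)
    day = day[ok]
    vals = df["value_pct_pred"].to_numpy(dtype=float)[ok]
    if len(np.unique(day)) < 4:
        raise DegenerateFitError(
            f"need >= 4 distinct days for a cubic fit, got {len(np.unique(day))}"
        )
    order = np.argsort(day)
    day, vals = day[order], vals[order]
    udays, idx = np.unique(day, return_inverse=True)
    means = np.bincount(idx, weights=vals) / np.bincount(idx)
    coef = np.polynomial.polynomial.polyfit(udays.astype(float), means, deg=3)
    fitted = np.polynomial.polynomial.polyval(udays.astype(float), coef)
    return DescriptiveCubic(coef=coef, days=udays, daily_means=means, fitted=fitted)
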