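"""Cohort data layer: I/O, baseline selection, subgrouping, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungtraj.cohort import (CohortReadWarning, DegenerateFitError, Measure,
                             MeasurementRecord, PatientBaseline, SchemaError,
                             TerminalEvent, TerminalEventType,
                             TerminalSubgroup, assign_terminal_subgroup,
                             fit_descriptive_trajectory, read_cohort,
                             select_baseline_measurement,
                             summarize_visit_patterns, write_cohort)


def _rec(pid="P1", t=0.0, value=70.0, measure=Measure.FVC):
    return MeasurementRecord(patient_id=pid, t=t, measure=measure,
                             value_pct_pred=value)


# ---------------------------------------------------------------------------
# record validation
# ---------------------------------------------------------------------------

def test_measurement_record_rejects_nonpositive_value():
    with pytest.raises(ValueError):
        _rec(value=0.0)
    with pytest.raises(ValueError):
        _rec(value=-5.0)


def test_patient_baseline_rejects_event_after_censoring():
    with pytest.raises(ValueError):
        PatientBaseline(
            patient_id="P1", censor_time=100.0,
            terminal_event=TerminalEvent(TerminalEventType.DEATH, 200.0))


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def test_read_cohort_round_trip(tmp_path):
    records = [
        MeasurementRecord("A", -10.0, Measure.FVC, 72.5, raw_value=2.9,
                          haemoglobin=None),
        MeasurementRecord("A", 120.0, Measure.DLCO, 43.1, haemoglobin=13.4),
        MeasurementRecord("B", 30.5, Measure.FVC, 88.0),
    ]
    baselines = [
        PatientBaseline("A", age=70.0, sex="male", bmi=28.9,
                        ever_smoked=True, censor_time=900.0,
                        terminal_event=TerminalEvent(
                            TerminalEventType.TRANSPLANT, 400.0)),
        PatientBaseline("B", age=65.5, sex="female", censor_time=1200.0),
    ]
    mp, bp = tmp_path / "m.csv", tmp_path / "b.csv"
    write_cohort(records, baselines, mp, bp)
    r2, b2 = read_cohort(mp, bp)
    assert r2 == records
    assert b2 == baselines
    # a second cycle reproduces the files byte-for-byte
    mp2, bp2 = tmp_path / "m2.csv", tmp_path / "b2.csv"
    write_cohort(r2, b2, mp2, bp2)
    assert mp.read_bytes() == mp2.read_bytes()
    assert bp.read_bytes() == bp2.read_bytes()


def test_read_cohort_missing_column_is_schema_error(tmp_path):
    mp = tmp_path / "m.csv"
    mp.write_text("t_days,measure,value_pct_pred\n0,FVC,70\n")
    bp = tmp_path / "b.csv"
    bp.write_text(",".join(
        ["patient_id", "age", "sex", "race_ethnicity", "bmi",
         "family_history_ild", "diagnostic_criteria", "prior_diagnosis",
         "oxygen_use", "antifibrotic", "ever_smoked", "osa",
         "enrolment_date", "event_type", "t_event_days", "censor_days"]) + "\n")
    with pytest.raises(SchemaError, match="patient_id"):
        read_cohort(mp, bp)


def test_read_cohort_flags_bad_row_and_keeps_others(tmp_path):
    mp = tmp_path / "m.csv"
    mp.write_text(
        "patient_id,t_days,measure,value_pct_pred,raw_value,haemoglobin\n"
        "A,0,FVC,70.0,,\n"
        "A,30,FVC,NA,,\n"
        "B,10,FVC,65.0,,\n")
    bp = tmp_path / "b.csv"
    header = ["patient_id", "age", "sex", "race_ethnicity", "bmi",
              "family_history_ild", "diagnostic_criteria", "prior_diagnosis",
              "oxygen_use", "antifibrotic", "ever_smoked", "osa",
              "enrolment_date", "event_type", "t_event_days", "censor_days"]
    bp.write_text(",".join(header) + "\nA,,,,,,,,,,,,,,,900\n")
    with pytest.warns(CohortReadWarning, match="row 3"):
        records, baselines = read_cohort(mp, bp)
    assert len(records) == 2
    assert {r.patient_id for r in records} == {"A", "B"}
    assert len(baselines) == 1


# ---------------------------------------------------------------------------
# baseline measurement selection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("times,expected", [
    ((-10.0, 20.0), -10.0),     # smaller |t| wins
    ((45.0,), None),            # outside the +/-30-day window
    ((-15.0, 15.0), -15.0),     # equidistant tie -> earlier record
    ((-31.0, 29.0), 29.0),      # window edge is inclusive on the inside
])
def test_select_baseline_measurement_cases(times, expected):
    records = [_rec(t=t, value=50.0 + i) for i, t in enumerate(times)]
    chosen = select_baseline_measurement(records, Measure.FVC)
    if expected is None:
        assert chosen is None
    else:
        assert chosen is not None and chosen.t == expected


def test_select_baseline_ignores_other_measure():
    records = [_rec(t=5.0, measure=Measure.DLCO)]
    assert select_baseline_measurement(records, Measure.FVC) is None


@settings(deadline=None, max_examples=50)
@given(st.permutations(list(range(6))))
def test_select_baseline_is_order_independent(perm):
    times = [-25.0, -12.0, -3.0, 3.0, 18.0, 29.0]
    records = [_rec(t=times[i]) for i in perm]
    chosen = select_baseline_measurement(records, Measure.FVC)
    assert chosen is not None and chosen.t == -3.0


def test_select_baseline_rejects_mixed_patients():
    with pytest.raises(ValueError):
        select_baseline_measurement([_rec(pid="A"), _rec(pid="B")], Measure.FVC)


# ---------------------------------------------------------------------------
# terminal-event subgroups
# ---------------------------------------------------------------------------

def _patient(event_type=None, t_event=None, censor=1500.0):
    ev = (TerminalEvent(event_type, t_event) if event_type else None)
    return PatientBaseline("P", censor_time=censor, terminal_event=ev)


@pytest.mark.parametrize("etype,t_event,censor,expected", [
    (TerminalEventType.DEATH, 304.0, 400.0, TerminalSubgroup.WITHIN_1Y),
    (TerminalEventType.WITHDRAWAL_WORSENING, 30 * 30.4375, 1000.0,
     TerminalSubgroup.Y2_TO_3),
    (None, None, 40 * 30.4375, TerminalSubgroup.NO_EVENT),
    (TerminalEventType.TRANSPLANT, 365.25, 400.0, TerminalSubgroup.WITHIN_1Y),
    (TerminalEventType.HOSPICE, 366.0, 400.0, TerminalSubgroup.Y1_TO_2),
    (TerminalEventType.DEATH, 3.1 * 365.25, 1500.0, TerminalSubgroup.AFTER_3Y),
])
def test_assign_terminal_subgroup(etype, t_event, censor, expected):
    assert assign_terminal_subgroup(_patient(etype, t_event, censor)) == expected


def test_subgroup_assignment_partitions_cohort(small_cohort):
    from lungtraj.cohort import frame_to_baselines
    baselines = frame_to_baselines(small_cohort.baseline)
    groups = [assign_terminal_subgroup(b) for b in baselines]
    counts = {g: groups.count(g) for g in TerminalSubgroup}
    assert sum(counts.values()) == len(baselines)
    assert counts[TerminalSubgroup.NO_EVENT] == int(
        (~small_cohort.baseline["event"]).sum())


# ---------------------------------------------------------------------------
# visit-pattern summaries
# ---------------------------------------------------------------------------

def test_visit_summary_hand_case():
    months = [0.0, 4.0, 9.0, 14.0]
    records = [_rec(t=m * 30.4375) for m in months]
    s = summarize_visit_patterns(records).per_measure[Measure.FVC]
    assert s.count_median == 4
    assert s.count_max == 4
    assert s.interval_months_median == pytest.approx(5.0)  # gaps 4, 5, 5


def test_visit_summary_two_patient_quantiles():
    records = [_rec(pid="A", t=30.0 * i) for i in range(2)]
    records += [_rec(pid="B", t=30.0 * i) for i in range(8)]
    s = summarize_visit_patterns(records).per_measure[Measure.FVC]
    # linear-interpolation quantiles of {2, 8}
    assert s.count_median == pytest.approx(5.0)
    assert s.count_q1 == pytest.approx(3.5)
    assert s.count_q3 == pytest.approx(6.5)


def test_visit_summary_matches_brute_force_recount(small_cohort):
    """Summary of a simulated cohort equals an independent recount."""
    df = small_cohort.measurements
    s = summarize_visit_patterns(df).per_measure[Measure.FVC]
    counts, gaps = [], []
    for _, g in df.groupby("patient_id"):
        t = sorted(g["t_days"])
        counts.append(len(t))
        gaps += [(b - a) / 30.4375 for a, b in zip(t, t[1:])]
    assert s.n_patients == len(counts)
    assert s.count_median == np.quantile(counts, 0.5)
    assert s.count_q1 == np.quantile(counts, 0.25)
    assert s.count_max == max(counts)
    assert s.interval_months_median == pytest.approx(np.quantile(gaps, 0.5))


def test_visit_summary_empty_cohort_errors():
    with pytest.raises(ValueError):
        summarize_visit_patterns(pd.DataFrame(
            columns=["patient_id", "t_days", "measure", "value_pct_pred"]))


# ---------------------------------------------------------------------------
# descriptive cubic through daily means
# ---------------------------------------------------------------------------

def test_descriptive_cubic_nests_linear_data():
    days = np.arange(0, 400, 10)
    records = [_rec(t=float(d), value=80.0 - 0.01 * d) for d in days]
    fit = fit_descriptive_trajectory(records, Measure.FVC)
    assert fit.coef == pytest.approx([80.0, -0.01, 0.0, 0.0], abs=1e-8)


def test_descriptive_cubic_exact_recovery():
    c = np.array([75.0, -0.02, 1e-5, -2e-8])
    days = np.arange(0, 500, 25)
    records = [_rec(t=float(d),
                    value=float(np.polynomial.polynomial.polyval(d, c)))
               for d in days]
    fit = fit_descriptive_trajectory(records, Measure.FVC)
    assert fit.coef == pytest.approx(c, rel=1e-6, abs=1e-10)


def test_descriptive_cubic_matches_normal_equations_oracle(small_cohort):
    """Noisy daily means: coefficients equal the closed-form LS solution."""
    fit = fit_descriptive_trajectory(small_cohort.measurements, Measure.FVC)
    V = np.vander(fit.days.astype(float), 4, increasing=True)
    oracle = np.linalg.solve(V.T @ V, V.T @ fit.daily_means)
    assert fit.coef == pytest.approx(oracle, rel=1e-6)


def test_descriptive_cubic_pools_same_day_values():
    # two values on day 0 from different patients enter as one pooled mean
    records = [_rec(pid="A", t=0.0, value=60.0), _rec(pid="B", t=0.0, value=80.0),
               _rec(pid="A", t=10.0, value=70.0), _rec(pid="A", t=20.0, value=70.0),
               _rec(pid="A", t=30.0, value=70.0)]
    fit = fit_descriptive_trajectory(records, Measure.FVC)
    assert fit.daily_means[0] == pytest.approx(70.0)


def test_descriptive_cubic_too_few_days():
    records = [_rec(t=float(d)) for d in (0, 10, 20)]
    with pytest.raises(DegenerateFitError):
        fit_descriptive_trajectory(records, Measure.FVC)
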