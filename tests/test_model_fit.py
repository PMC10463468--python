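"""Fitting behaviour: recovery on easy data, optimizer contract, Wald tests,
trajectory identities and the modified baseline-value model."""

import warnings

import numpy as np
import pandas as pd
import pytest

from lungtraj.cohort import DAYS_PER_YEAR
from lungtraj.likelihood import ModelSpec
from lungtraj.model import (BaselineValueTrajectoryModel, JointTrajectoryModel,
                            encode_covariates, estimate_mean_trajectory,
                            fit_joint_model, wald_interaction_tests)
from lungtraj.params import JointModelParams
from lungtraj.simulate import (fvc_reference_params,
                               simulate_baseline_value_cohort, simulate_cohort)


def _sex_generator(n, rng):
    return pd.DataFrame({"sex_male": (rng.random(n) < 0.74).astype(float)})


def _with_sex(base, beta_sex=0.0, theta_sex=0.0, alpha_sex=0.0, phi_sex=0.0):
    return JointModelParams(**{
        **base.to_dict(), "alpha": [alpha_sex],
        "beta": [base.beta[0], beta_sex], "theta": [theta_sex],
        "phi": [phi_sex]})


@pytest.fixture(scope="module")
def sex_effect_fit(fvc_truth):
    """One fit of a cohort where males decline 1.5 %/yr faster."""
    truth = _with_sex(fvc_truth, beta_sex=-4.0, theta_sex=-1.5)
    sim = simulate_cohort(truth, 400, np.random.default_rng(21),
                          covariate_columns=("sex_male",),
                          covariate_generator=_sex_generator)
    est = JointTrajectoryModel(
        covariates=("sex_male",), interactions=("sex_male",),
        visit_covariates=("sex_male",), hazard_covariates=("sex_male",))
    est.fit(sim.measurements, sim.baseline)
    return truth, sim, est


def test_fit_is_deterministic(fvc_truth):
    sim = simulate_cohort(fvc_truth, 80, np.random.default_rng(30))
    a = JointTrajectoryModel(compute_se=False).fit(sim.measurements, sim.baseline)
    b = JointTrajectoryModel(compute_se=False).fit(sim.measurements, sim.baseline)
    assert np.array_equal(a.params_.to_vector(), b.params_.to_vector())
    assert a.loglik_ == b.loglik_


def test_accepted_step_loglik_non_decreasing(fvc_truth):
    sim = simulate_cohort(fvc_truth, 120, np.random.default_rng(31))
    est = JointTrajectoryModel(compute_se=False).fit(sim.measurements,
                                                     sim.baseline)
    trace = est.result_.trace
    assert len(trace) > 3
    assert np.all(np.diff(trace) >= -1e-7)
    assert trace[-1] == pytest.approx(est.loglik_, abs=1e-6)


def test_null_associations_recovered_unbiased(fvc_truth):
    """Data with gamma1 = gamma2 = gamma3 = 0 yield estimates centred on 0:
    each association's replicate mean stays within 2.5 standard errors of
    its own Monte-Carlo spread."""
    null = JointModelParams(**{**fvc_truth.to_dict(), "gamma1": 0.0,
                               "gamma2": 0.0, "gamma3": 0.0})
    ests = {g: [] for g in ("gamma1", "gamma2", "gamma3")}
    for rng in np.random.default_rng(32).spawn(6):
        sim = simulate_cohort(null, 400, rng)
        result = fit_joint_model(sim.measurements, sim.baseline,
                                 compute_se=False)
        for g in ests:
            ests[g].append(result.estimate_for(g))
    for g, vals in ests.items():
        vals = np.asarray(vals)
        bound = 2.5 * vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < bound, (g, vals)


def test_sex_interaction_recovered_and_detected(sex_effect_fit):
    truth, sim, est = sex_effect_fit
    theta_hat = est.result_.estimate_for("theta:sex_male")
    se = est.result_.se_for("theta:sex_male")
    assert theta_hat == pytest.approx(-1.5, abs=3 * se)
    wald = est.result_.wald
    assert set(wald["covariate"]) == {"sex_male"}
    p = wald["interaction_p"].iloc[0]
    assert 0.0 <= p <= 1.0
    assert p < 0.05  # a 1.5 %/yr difference is easily detected at n=400
    # main-effect p suppressed (NaN) when the interaction is significant
    assert np.isnan(wald["main_p"].iloc[0])


def test_trajectory_subgroup_identities(sex_effect_fit):
    """Linear-model trajectory: subgroup slope difference equals theta and
    intercept difference equals the sex main effect, exactly."""
    truth, sim, est = sex_effect_fit
    baseline = sim.baseline
    traj = estimate_mean_trajectory(est.result_, baseline, subgroup="sex_male",
                                    horizon_days=365)
    p = est.params_
    assert traj.slope_difference("1.0", "0.0") == pytest.approx(
        float(p.theta[0]), abs=1e-10)
    assert traj.intercept_difference("1.0", "0.0") == pytest.approx(
        float(p.beta[1]), abs=1e-10)
    # male decline steeper, mirroring the generative truth
    assert traj.slopes["1.0"] < traj.slopes["0.0"]
    # daily means lie exactly on the line
    curve = traj.overall
    assert np.allclose(np.diff(curve, 2), 0.0, atol=1e-12)
    assert traj.intercepts["overall"] == pytest.approx(curve[0])


def test_trajectory_intercept_only_slope_equals_delta(fvc_truth):
    sim = simulate_cohort(fvc_truth, 150, np.random.default_rng(33))
    result = fit_joint_model(sim.measurements, sim.baseline, compute_se=False)
    traj = estimate_mean_trajectory(result, None, horizon_days=730)
    slope_daily = (traj.overall[-1] - traj.overall[0]) / (
        (traj.days[-1] - traj.days[0]) / DAYS_PER_YEAR)
    assert slope_daily == pytest.approx(result.params.delta, abs=1e-9)


def test_trajectory_empty_subgroup_errors(sex_effect_fit):
    _, sim, est = sex_effect_fit
    with pytest.raises((ValueError, KeyError)):
        estimate_mean_trajectory(est.result_, sim.baseline,
                                 subgroup="not_a_column")


def test_wald_unknown_covariate_is_key_error(sex_effect_fit):
    _, _, est = sex_effect_fit
    with pytest.raises(KeyError):
        wald_interaction_tests(est.result_, groups={"bmi": ["bmi"]})


def test_quadratic_time_term_not_detected_on_linear_truth(fvc_truth):
    """Polynomial-time check: data simulated linear in time yield a
    non-significant quadratic Wald test in most replicates."""
    rejections = 0
    for rng in np.random.default_rng(55).spawn(10):
        sim = simulate_cohort(fvc_truth, 250, rng)
        result = fit_joint_model(sim.measurements, sim.baseline,
                                 spec=ModelSpec(time_degree=2))
        z = result.estimate_for("time^2") / result.se_for("time^2")
        if z * z > 3.841:  # chi2(1) at 5%
            rejections += 1
    assert rejections <= 2


def test_joint_model_beats_naive_mixed_model_under_informative_sampling(
        fvc_truth):
    """At the reference associations, a plain random-intercept mixed model
    attenuates the slope (survivors are healthier); the joint fit does not."""
    import statsmodels.formula.api as smf
    naive, joint = [], []
    for rng in np.random.default_rng(202).spawn(6):
        sim = simulate_cohort(fvc_truth, 500, rng)
        df = sim.measurements.copy()
        df["tau"] = df["t_days"] / DAYS_PER_YEAR
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mm = smf.mixedlm("value_pct_pred ~ tau", df,
                             groups=df["patient_id"]).fit()
        est = JointTrajectoryModel(compute_se=False).fit(sim.measurements,
                                                         sim.baseline)
        naive.append(mm.params["tau"])
        joint.append(est.params_.delta)
    bias_naive = abs(np.mean(naive) - fvc_truth.delta)
    bias_joint = abs(np.mean(joint) - fvc_truth.delta)
    assert bias_naive > bias_joint


# ---------------------------------------------------------------------------
# baseline-value model
# ---------------------------------------------------------------------------

def test_baseline_value_model_recovers_slope_function():
    sim = simulate_baseline_value_cohort(400, np.random.default_rng(40))
    est = BaselineValueTrajectoryModel(compute_se=False)
    est.fit(sim.measurements, sim.baseline)
    assert est.n_excluded_ == 0
    assert est.annual_decline_at(60.0) == pytest.approx(2.5, abs=0.45)
    assert est.annual_decline_at(80.0) == pytest.approx(2.9, abs=0.45)
    # slope function is linear in b by construction
    s60, s70, s80 = (est.slope_at(b) for b in (60.0, 70.0, 80.0))
    assert s70 - s60 == pytest.approx(s80 - s70, abs=1e-12)


def test_baseline_value_model_excludes_patients_without_enrolment_value():
    sim = simulate_baseline_value_cohort(120, np.random.default_rng(41))
    drop = sim.measurements["patient_id"].iloc[0]
    m = sim.measurements[~((sim.measurements["patient_id"] == drop)
                           & (sim.measurements["t_days"] == 0.0))]
    est = BaselineValueTrajectoryModel(compute_se=False)
    est.fit(m, sim.baseline)
    assert est.n_excluded_ == 1


def test_encode_covariates_reference_levels():
    df = pd.DataFrame({
        "patient_id": list("abcd"),
        "sex": ["male", "female", "male", "female"],
        "oxygen_use": ["none", "activity_only", "activity_and_rest", "none"],
        "bmi": [25.0, 30.0, 28.0, 31.0],
        "osa": [True, False, True, False],
    })
    out, groups = encode_covariates(df, ["sex", "oxygen_use", "bmi", "osa"])
    assert groups["sex"] == ["sex__male"]          # reference: female
    assert set(groups["oxygen_use"]) == {"oxygen_use__activity_only",
                                         "oxygen_use__activity_and_rest"}
    assert groups["bmi"] == ["bmi"] and groups["osa"] == ["osa"]
    assert out["sex__male"].tolist() == [1.0, 0.0, 1.0, 0.0]
    assert out["osa"].dtype == float
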