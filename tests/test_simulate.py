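"""Generator checks: visit process, event times, longitudinal values and the
cross-process associations induced by the shared random effects."""

import numpy as np
import pytest
from scipy import stats

from lungtraj.cohort import DAYS_PER_YEAR
from lungtraj.params import JointModelParams
from lungtraj.simulate import (dlco_reference_params, expected_visit_count,
                               fvc_reference_params,
                               generate_registry_covariates,
                               simulate_baseline_value_cohort, simulate_cohort,
                               simulate_event_time, simulate_visit_times)


# ---------------------------------------------------------------------------
# visit process
# ---------------------------------------------------------------------------

def _mean_count(u, lp, lam, knots, horizon_years, reps=10_000, seed=0):
    rng = np.random.default_rng(seed)
    counts = [simulate_visit_times(u, lp, lam, knots,
                                   horizon_years * DAYS_PER_YEAR, rng).size
              for _ in range(reps)]
    counts = np.asarray(counts)
    return counts.mean(), counts.std(ddof=1) / np.sqrt(reps)


def test_homogeneous_poisson_mean_count():
    mean, se = _mean_count(0.0, 0.0, [2.0], [0.0], 3.0)
    assert abs(mean - 6.0) < 3 * se


def test_frailty_multiplies_intensity():
    mean, se = _mean_count(0.7, 0.0, [2.0], [0.0], 3.0, seed=1)
    assert abs(mean - 6.0 * np.exp(0.7)) < 3 * se


def test_two_piece_intensity_matches_thinning_oracle():
    """Piecewise inversion vs an independent thinning simulator."""
    lam, knots, horizon = np.array([2.0, 4.0]), np.array([0.0, 1.0]), 2.0
    mean, se = _mean_count(0.0, 0.0, lam, knots, horizon, seed=2)

    def thinning_counts(reps, seed):
        rng = np.random.default_rng(seed)
        lam_max = lam.max()
        out = np.empty(reps)
        for r in range(reps):
            t, k = 0.0, 0
            while True:
                t += rng.exponential(1.0 / lam_max)
                if t > horizon:
                    break
                rate = lam[np.searchsorted(knots, t, side="right") - 1]
                if rng.random() < rate / lam_max:
                    k += 1
            out[r] = k
        return out

    oracle = thinning_counts(10_000, seed=3)
    se_tot = np.sqrt(se ** 2 + oracle.var(ddof=1) / oracle.size)
    assert abs(mean - oracle.mean()) < 3 * se_tot
    assert abs(mean - 6.0) < 3 * se  # analytic total intensity 2*1 + 4*1


def test_visit_times_rejects_negative_intensity():
    with pytest.raises(ValueError):
        simulate_visit_times(0.0, 0.0, [-1.0], [0.0], 365.0, 0)


def test_visit_times_reproducible_under_seed():
    a = simulate_visit_times(0.3, 0.0, [2.4], [0.0], 1000.0, 7)
    b = simulate_visit_times(0.3, 0.0, [2.4], [0.0], 1000.0, 7)
    assert np.array_equal(a, b)
    assert np.all(np.diff(a) >= 0) and np.all((a >= 0) & (a <= 1000.0))


# ---------------------------------------------------------------------------
# expected visit count
# ---------------------------------------------------------------------------

def test_expected_visit_count_arithmetic():
    p = JointModelParams(log_lambda0=np.log([2.0]), sigma2_u=0.0)
    assert expected_visit_count(p, None, 3 * DAYS_PER_YEAR) == pytest.approx(6.0)
    p2 = JointModelParams(log_lambda0=np.log([2.0]), sigma2_u=0.53)
    assert expected_visit_count(p2, None, 3 * DAYS_PER_YEAR) \
        == pytest.approx(6.0 * np.exp(0.265))
    assert expected_visit_count(p2, None, 3 * DAYS_PER_YEAR) \
        == pytest.approx(7.820, abs=5e-3)


def test_expected_visit_count_matches_simulation():
    """Marginal mean over frailty draws matches the lognormal formula."""
    p = JointModelParams(log_lambda0=np.log([2.4]), sigma2_u=0.53)
    rng = np.random.default_rng(5)
    n = 10_000
    u = rng.normal(0, np.sqrt(p.sigma2_u), n)
    horizon = 2 * DAYS_PER_YEAR
    counts = np.array([
        simulate_visit_times(ui, 0.0, [2.4], [0.0], horizon, rng).size
        for ui in u])
    se = counts.std(ddof=1) / np.sqrt(n)
    assert abs(counts.mean() - expected_visit_count(p, None, horizon)) < 3 * se


# ---------------------------------------------------------------------------
# terminal-event times
# ---------------------------------------------------------------------------

def test_event_time_matches_discrete_hazard_oracle():
    """Inversion sampler vs a fine-grid discrete-hazard simulator (KS)."""
    h0, knots = np.array([0.3, 0.8]), np.array([0.0, 1.5])
    rng = np.random.default_rng(11)
    draws = np.array([simulate_event_time(0.2, h0, knots, rng)
                      for _ in range(10_000)]) / DAYS_PER_YEAR

    grid_rng = np.random.default_rng(12)
    dt = 1e-3
    grid = np.arange(0, 40.0, dt)
    rates = np.where(grid < 1.5, 0.3, 0.8) * np.exp(0.2)
    # directly invert the discrete cumulative hazard for independent draws
    cumhaz = np.cumsum(rates * dt)
    e = grid_rng.exponential(size=10_000)
    oracle = grid[np.searchsorted(cumhaz, e).clip(max=len(grid) - 1)]
    ks = stats.ks_2samp(draws, oracle)
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# full cohort generation
# ---------------------------------------------------------------------------

def test_noise_free_cohort_lies_on_slope_line():
    p = JointModelParams(
        log_lambda0=np.log([3.0]), sigma2_u=0.0, beta=np.array([72.9]),
        delta=-2.8, gamma1=0.0, sigma2_v=0.0, sigma2_e=0.0,
        log_h0=np.log([1e-8]), gamma2=0.0, gamma3=0.0)
    sim = simulate_cohort(p, 20, np.random.default_rng(0))
    df = sim.measurements
    slope = (df["value_pct_pred"] - 72.9) / (df["t_days"] / DAYS_PER_YEAR)
    ok = df["t_days"] > 1.0
    assert np.allclose(slope[ok], -2.8, atol=1e-9)


def test_intercept_only_mean_near_enrolment(fvc_truth):
    # without shared-effect loadings the early-visit mean is unconfounded
    p = JointModelParams(**{**fvc_truth.to_dict(),
                            "gamma1": 0.0, "gamma2": 0.0, "gamma3": 0.0})
    sim = simulate_cohort(p, 4000, np.random.default_rng(8))
    early = sim.measurements[sim.measurements["t_days"] < 60.0]
    se = early["value_pct_pred"].std() / np.sqrt(len(early))
    # small allowance for the -2.8/yr trend over the first 60 days
    assert abs(early["value_pct_pred"].mean() - 72.9) < 3 * se + 0.3


def _first_year_stats(sim):
    """Visit count over a fixed one-year exposure window (patients followed
    at least a year), the patient's mean value, and later event occurrence.

    Conditioning on equal exposure removes the mechanical truncation of
    counts by early terminal events, isolating the frailty-driven
    associations.
    """
    base = sim.baseline
    m = sim.measurements
    fup = np.where(base["event"], base["t_event_days"], base["censor_days"])
    ok = fup >= DAYS_PER_YEAR
    year1 = m[m["t_days"] <= DAYS_PER_YEAR].groupby("patient_id").size()
    count = base["patient_id"].map(year1).fillna(0)[ok]
    mean_y = base["patient_id"].map(
        m.groupby("patient_id")["value_pct_pred"].mean())[ok]
    later_event = (base["event"] & (base["t_event_days"] > DAYS_PER_YEAR))[ok]
    keep = mean_y.notna()
    return count[keep], mean_y[keep], later_event[keep].astype(int)


def test_gamma1_induces_negative_count_value_correlation(fvc_truth):
    """Sicker patients (low values) are tested more often (gamma1 < 0)."""
    sim = simulate_cohort(fvc_truth, 2000, np.random.default_rng(9))
    count, mean_y, _ = _first_year_stats(sim)
    assert stats.spearmanr(count, mean_y).statistic < -0.1


def test_gamma2_links_visit_count_to_events(fvc_truth):
    """Higher testing frequency goes with higher terminal-event risk."""
    sim = simulate_cohort(fvc_truth, 2000, np.random.default_rng(10))
    count, _, later_event = _first_year_stats(sim)
    assert stats.spearmanr(count, later_event).statistic > 0.1


def test_zero_gammas_decouple_processes(fvc_truth):
    p = JointModelParams(**{**fvc_truth.to_dict(),
                            "gamma1": 0.0, "gamma2": 0.0, "gamma3": 0.0})
    sim = simulate_cohort(p, 3000, np.random.default_rng(13))
    count, mean_y, later_event = _first_year_stats(sim)
    assert abs(stats.spearmanr(count, mean_y).statistic) < 0.06
    assert abs(stats.spearmanr(count, later_event).statistic) < 0.06


def test_measurements_respect_followup(fvc_truth):
    sim = simulate_cohort(fvc_truth, 300, np.random.default_rng(14))
    base = sim.baseline.set_index("patient_id")
    fup = np.where(base["event"], base["t_event_days"], base["censor_days"])
    fup = dict(zip(base.index, fup))
    assert all(t <= fup[p] for p, t in
               zip(sim.measurements["patient_id"], sim.measurements["t_days"]))
    # latent truth is recorded for every patient
    assert set(sim.latent["patient_id"]) == set(base.index)


def test_cohort_reproducible_under_seed(fvc_truth):
    a = simulate_cohort(fvc_truth, 50, 123)
    b = simulate_cohort(fvc_truth, 50, 123)
    assert a.measurements.equals(b.measurements)
    assert a.baseline.equals(b.baseline)


def test_registry_covariate_frequencies():
    covs = generate_registry_covariates(20_000, np.random.default_rng(1))
    assert (covs["sex"] == "male").mean() == pytest.approx(0.74, abs=0.02)
    assert covs["antifibrotic"].mean() == pytest.approx(0.52, abs=0.02)
    assert covs["age"].median() == pytest.approx(70.0, abs=0.5)
    assert set(covs["oxygen_use"]) == {"none", "activity_only",
                                       "activity_and_rest"}


def test_baseline_value_cohort_structure():
    sim = simulate_baseline_value_cohort(200, np.random.default_rng(2))
    enrol = sim.measurements[sim.measurements["t_days"] == 0.0]
    assert len(enrol) == 200
    merged = enrol.merge(sim.baseline, on="patient_id")
    assert np.allclose(merged["value_pct_pred"], merged["baseline_value"])
    assert np.allclose(sim.baseline["baseline_centred"],
                       sim.baseline["baseline_value"] - 60.0)
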