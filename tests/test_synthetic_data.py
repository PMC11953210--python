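"""Simulator, analytic tilt oracle, calibration, and fixture construction."""

import math

import numpy as np
import pytest

from osteofrailia import (
    ArmSpec,
    InputError,
    RiskModel,
    SimulationSpec,
    calibrate_baseline_risk,
    expected_case_mean_shift,
    expected_incidence,
    fixture_cohort_from_marginals,
    sensitivity_at_threshold,
    simulate_cohort,
    simulate_population,
)


def arm(mean_t=-1.25, sd_t=1.0, n=1000, beta=0.7, p0=0.03, label="a", sex="M"):
    return ArmSpec(label=label, sex=sex, mean_t=mean_t, sd_t=sd_t, n=n,
                   risk_model=RiskModel(beta, p0))


class TestRiskModel:
    def test_invariants(self):
        with pytest.raises(InputError):
            RiskModel(-0.1, 0.05)
        with pytest.raises(InputError):
            RiskModel(0.5, 1.0)

    def test_strictly_decreasing_and_bounded(self):
        m = RiskModel(0.7, 0.05)
        t = np.linspace(-6, 4, 50)
        r = m.risk(t)
        assert np.all(np.diff(r) < 0)
        assert np.all((r > 0) & (r < 1))
        assert m.risk(0.0) == pytest.approx(0.05)

    def test_beta_zero_is_flat(self):
        m = RiskModel(0.0, 0.05)
        assert m.risk(-5.0) == pytest.approx(0.05)
        assert m.risk(3.0) == pytest.approx(0.05)


class TestSimulatePopulation:
    def test_sample_mean_within_standard_error(self):
        a = arm(mean_t=-1.25, sd_t=1.0, n=100_000)
        t = simulate_population(a, seed=17)
        assert abs(t.mean() + 1.25) < 3 / math.sqrt(100_000)
        assert abs(t.std(ddof=1) - 1.0) < 0.01

    def test_zero_sd_rejected(self):
        with pytest.raises(InputError):
            arm(sd_t=0.0)

    def test_seeded_determinism(self):
        a = arm(n=500)
        assert np.array_equal(simulate_population(a, 9), simulate_population(a, 9))
        spec = SimulationSpec((arm(n=500), arm(label="b", sex="F", n=400)), seed=3)
        c1, c2 = simulate_cohort(spec), simulate_cohort(spec)
        assert c1.data.equals(c2.data)


class TestSimulateCohort:
    def test_flat_risk_gives_baseline_incidence(self):
        spec = SimulationSpec((arm(beta=0.0, p0=0.05, n=50_000),), seed=21)
        cohort = simulate_cohort(spec)
        p_hat = cohort.n_cases / len(cohort)
        se = math.sqrt(0.05 * 0.95 / 50_000)
        assert abs(p_hat - 0.05) < 3 * se

    def test_cases_have_lower_baseline_than_noncases(self):
        spec = SimulationSpec((arm(beta=1.0, p0=0.05, n=50_000),), seed=22)
        cohort = simulate_cohort(spec)
        df = cohort.data
        assert df.loc[df.fracture, "baseline_t"].mean() < df.loc[~df.fracture, "baseline_t"].mean()

    def test_calibrated_spec_reproduces_case_count_anchor(self):
        """A spec calibrated to the Hong Kong male incidence (63/2000 over
        follow-up) yields ≈63 cases at n = 2000, within binomial error."""
        target = 63 / 2000
        p0 = calibrate_baseline_risk(-1.25, 0.8846, 0.7, target)
        spec = SimulationSpec((arm(mean_t=-1.25, sd_t=0.8846, beta=0.7, p0=p0, n=2000),),
                              seed=2001)
        cohort = simulate_cohort(spec)
        sd = math.sqrt(2000 * target * (1 - target))
        assert abs(cohort.n_cases - 63) < 3 * sd


class TestTiltOracle:
    def test_beta_zero_returns_population_mean(self):
        assert expected_case_mean_shift(-1.25, 1.0, RiskModel(0.0, 0.03)) == pytest.approx(-1.25)

    def test_rare_event_limit_matches_tilt_formula(self):
        """At baseline risk 0.005 the case mean is within 1% of the
        exponential-tilting value mean − β·σ²."""
        for mean_t, sd_t, beta in ((-1.25, 1.0, 0.7), (-1.76, 0.9, 0.5), (-1.717, 1.0, 0.7)):
            got = expected_case_mean_shift(mean_t, sd_t, RiskModel(beta, 0.005))
            tilt = mean_t - beta * sd_t**2
            assert abs(got - tilt) <= 0.01 * abs(tilt)

    def test_brute_force_grid_oracle(self):
        """Independent check: a dense-grid Riemann evaluation of
        E[T·risk]/E[risk] agrees with the adaptive quadrature."""
        mean_t, sd_t = -1.5, 0.9
        model = RiskModel(0.8, 0.04)
        t = np.linspace(mean_t - 12 * sd_t, mean_t + 12 * sd_t, 400_001)
        pdf = np.exp(-0.5 * ((t - mean_t) / sd_t) ** 2) / (sd_t * math.sqrt(2 * math.pi))
        w = model.risk(t) * pdf
        grid_value = np.trapezoid(t * w, t) / np.trapezoid(w, t)
        assert expected_case_mean_shift(mean_t, sd_t, model) == pytest.approx(
            grid_value, abs=1e-8
        )

    def test_simulated_case_mean_matches_oracle(self):
        """Simulated fracture-case mean agrees with the integral oracle
        within 3 standard errors at n = 10⁶."""
        mean_t, sd_t, beta, p0 = -1.25, 1.0, 0.7, 0.02
        spec = SimulationSpec((arm(mean_t=mean_t, sd_t=sd_t, beta=beta, p0=p0, n=1_000_000),),
                              seed=77)
        cohort = simulate_cohort(spec)
        cases = cohort.data.loc[cohort.data.fracture, "baseline_t"]
        pred = expected_case_mean_shift(mean_t, sd_t, RiskModel(beta, p0))
        se = cases.std(ddof=1) / math.sqrt(len(cases))
        assert abs(cases.mean() - pred) < 3 * se

    def test_parallelism_between_sexes(self):
        """Two sexes with equal β and σ: the case-mean difference equals
        the population-mean difference — analytically via the oracle, and
        in simulation within Monte-Carlo error."""
        beta, sd_t, p0 = 0.7, 1.0, 0.005
        delta_pop = 0.476
        m_mean, f_mean = -1.241, -1.241 - delta_pop
        shift_m = expected_case_mean_shift(m_mean, sd_t, RiskModel(beta, p0))
        shift_f = expected_case_mean_shift(f_mean, sd_t, RiskModel(beta, p0))
        assert shift_m - shift_f == pytest.approx(delta_pop, abs=0.005)

        spec = SimulationSpec(
            (
                arm(mean_t=m_mean, sd_t=sd_t, beta=beta, p0=p0, n=400_000, label="m", sex="M"),
                arm(mean_t=f_mean, sd_t=sd_t, beta=beta, p0=p0, n=400_000, label="f", sex="F"),
            ),
            seed=88,
        )
        df = simulate_cohort(spec).data
        case_means = df[df.fracture].groupby("sex")["baseline_t"].agg(["mean", "std", "count"])
        diff = case_means.loc["M", "mean"] - case_means.loc["F", "mean"]
        se = math.sqrt(sum(case_means["std"] ** 2 / case_means["count"]))
        assert abs(diff - delta_pop) < 3 * se


class TestCalibration:
    def test_beta_zero_returns_target_exactly(self):
        assert calibrate_baseline_risk(-1.25, 1.0, 0.0, 0.03) == pytest.approx(0.03, abs=1e-9)

    def test_round_trip_incidence(self):
        p0 = calibrate_baseline_risk(-1.76, 1.07, 0.6, 69 / 2000)
        got = expected_incidence(-1.76, 1.07, RiskModel(0.6, p0))
        assert got == pytest.approx(69 / 2000, abs=1e-6)

    def test_two_to_one_incidence_ratio_in_simulation(self):
        """Calibrating female incidence to twice the male target yields a
        simulated case ratio of ≈2:1 within binomial error."""
        beta, sd_t, n = 0.7, 1.0, 300_000
        male_target, female_target = 0.02, 0.04
        p0_m = calibrate_baseline_risk(-1.241, sd_t, beta, male_target)
        p0_f = calibrate_baseline_risk(-1.717, sd_t, beta, female_target)
        spec = SimulationSpec(
            (
                arm(mean_t=-1.241, sd_t=sd_t, beta=beta, p0=p0_m, n=n, label="m", sex="M"),
                arm(mean_t=-1.717, sd_t=sd_t, beta=beta, p0=p0_f, n=n, label="f", sex="F"),
            ),
            seed=99,
        )
        df = simulate_cohort(spec).data
        cases = df.groupby("sex")["fracture"].sum()
        # 3-sigma interval on the ratio via error propagation
        ratio = cases["F"] / cases["M"]
        se = ratio * math.sqrt(1 / cases["F"] + 1 / cases["M"])
        assert abs(ratio - 2.0) < 3 * se

    def test_invalid_target_rejected(self):
        with pytest.raises(InputError):
            calibrate_baseline_risk(-1.25, 1.0, 0.7, 0.0)


class TestFixtureFromMarginals:
    def test_exact_count_reproduction(self, hk_cohorts):
        m = hk_cohorts["M"]
        assert (len(m), m.n_cases) == (2000, 63)
        assert sensitivity_at_threshold(m, -2.7).numerator == 10
        assert sensitivity_at_threshold(m, -2.1).numerator == 29

    def test_deterministic_same_marginals_same_table(self):
        kw = dict(n=200, cases=20, case_counts_below={-2.5: 5},
                  population_counts_below={-2.5: 30}, sex="F")
        a = fixture_cohort_from_marginals(**kw)
        b = fixture_cohort_from_marginals(**kw)
        assert a.data.equals(b.data)

    def test_inconsistent_marginals_rejected(self):
        with pytest.raises(InputError):
            # more below-threshold cases than cases
            fixture_cohort_from_marginals(100, 10, {-2.5: 15})
        with pytest.raises(InputError):
            # decreasing counts with increasing threshold
            fixture_cohort_from_marginals(100, 50, {-2.7: 30, -2.1: 10})
        with pytest.raises(InputError):
            # population count below the case count at the same threshold
            fixture_cohort_from_marginals(100, 50, {-2.5: 30},
                                          population_counts_below={-2.5: 20})

    def test_sensitivity_dominates_prevalence_when_cases_sit_lower(self, hk_cohorts):
        """With a positive risk gradient, fracture cases sit stochastically
        lower, so capture fraction ≥ cohort prevalence at any threshold."""
        for cohort in hk_cohorts.values():
            for threshold in (-3.0, -2.7, -2.1, -1.5):
                sens = sensitivity_at_threshold(cohort, threshold).fraction
                prev = (cohort.data["baseline_t"] <= threshold).mean()
                assert sens >= prev
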