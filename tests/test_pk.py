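"""One-compartment model: parameter priors, creatinine excretion, the analytic
hourly serum recursion and the urine/bladder transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from pkabc import pk
from pkabc.config import CreatinineFormula, PKPriors, PointEstimates

POINTS = PointEstimates()


def point_params(n_creatinine=50.0):
    return pk.point_estimate_parameters(POINTS).with_creatinine(n_creatinine)


class TestParameterSampling:
    def test_prior_means_match_table(self, rng):
        n = 100_000
        params = pk.sample_pk_parameters(rng, PKPriors(), size=n)
        # V ~ Gamma(6.78, rate 0.38): mean 17.84, var shape/rate^2
        v_mean, v_sd = 6.78 / 0.38, np.sqrt(6.78) / 0.38
        assert abs(params.v.mean() - v_mean) < 3 * v_sd / np.sqrt(n)
        # f ~ Beta(11.1, 31.4): mean 0.2612
        f_mean = 11.1 / 42.5
        f_sd = np.sqrt(f_mean * (1 - f_mean) / 43.5)
        assert abs(params.f.mean() - f_mean) < 3 * f_sd / np.sqrt(n)
        # half-life ~ Gamma(24.2, 3.79): mean 6.385 h -> k centred near 0.108
        hl = np.log(2) / params.k
        hl_mean, hl_sd = 24.2 / 3.79, np.sqrt(24.2) / 3.79
        assert abs(hl.mean() - hl_mean) < 3 * hl_sd / np.sqrt(n)
        assert set(np.unique(params.void_interval)) == {4, 5, 6}

    def test_point_estimate_mode(self):
        p = pk.point_estimate_parameters(POINTS)
        assert (p.k, p.f, p.v, p.r, p.void_interval) == (0.108, 0.25, 17.7, 0.58, 5)

    def test_draws_are_valid(self, rng):
        p = pk.sample_pk_parameters(rng, PKPriors(), size=1000)
        assert np.all((p.k > 0) & (p.f > 0) & (p.f < 1) & (p.v > 0))
        assert np.all((p.r > 0) & (p.r < 1))


class TestCreatinineExcretion:
    def test_adult_formula_hand_evaluation(self):
        # default adult branch: 0.20 * (140 - age) * weight mg/day
        expected = 0.20 * (140 - 30) * 80.0 / 24.0
        got = pk.creatinine_excretion_rate(30.0, "male", 80.0, 180.0)
        assert got == pytest.approx(expected)
        female = pk.creatinine_excretion_rate(30.0, "female", 80.0, 180.0)
        assert female == pytest.approx(expected * 0.85)

    def test_per_day_is_24x_per_hour(self):
        per_h = pk.creatinine_excretion_rate(30.0, "male", 80.0, 180.0, per="hour")
        per_d = pk.creatinine_excretion_rate(30.0, "male", 80.0, 180.0, per="day")
        assert per_d == pytest.approx(24.0 * per_h)

    def test_child_branch_engaged_iff_age_at_most_18(self):
        formula = CreatinineFormula()
        child = pk.creatinine_excretion_rate(18.0, "male", 60.0, 170.0, formula, per="day")
        adult = pk.creatinine_excretion_rate(18.01, "male", 60.0, 170.0, formula, per="day")
        assert child == pytest.approx(
            (formula.child_intercept + formula.child_slope * 18.0) * 60.0
        )
        assert adult == pytest.approx(0.20 * (140 - 18.01) * 60.0)

    def test_unsupported_age_errors(self):
        with pytest.raises(ValueError, match="age"):
            pk.creatinine_excretion_rate(150.0, "male", 80.0, 180.0)


class TestSerumSeries:
    def test_pure_decay_closed_form(self):
        serum = pk.serum_series(np.zeros(5), k=0.108, f=0.25, v=17.7, c0=1.0)
        np.testing.assert_allclose(serum, np.exp(-0.108 * np.arange(6)), rtol=1e-12)
        assert serum[1] == pytest.approx(0.8977, abs=2e-4)

    def test_constant_rate_converges_to_steady_state(self):
        d = 0.4  # mg/h
        serum = pk.serum_series(np.full(2000, d), k=0.108, f=0.25, v=17.7)
        target = 0.25 * d / (0.108 * 17.7)
        assert serum[-1] == pytest.approx(target, rel=1e-6)

    def test_superposition(self, rng):
        a = rng.uniform(0, 0.5, 48)
        b = rng.uniform(0, 0.5, 48)
        kw = dict(k=0.2, f=0.3, v=15.0)
        s_ab = pk.serum_series(a + b, **kw, c0=0.5)
        s_a = pk.serum_series(a, **kw, c0=0.5)
        s_b = pk.serum_series(b, **kw, c0=0.0)
        np.testing.assert_allclose(s_ab, s_a + s_b, rtol=1e-10)

    def test_matches_fine_step_ode_integration(self, rng):
        k, f, v = 0.15, 0.3, 12.0
        doses = rng.uniform(0, 0.2, 36) * (rng.random(36) < 0.3)
        c0 = 0.01
        analytic = pk.serum_series(doses, k, f, v, c0)
        c = c0
        numeric = [c0]
        for d in doses:
            sol = solve_ivp(
                lambda t, y: f * d / v - k * y, (0, 1), [c],
                rtol=1e-11, atol=1e-14, dense_output=False,
            )
            c = sol.y[0, -1]
            numeric.append(c)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            pk.serum_series(np.array([-0.1]), 0.1, 0.25, 17.7)


class TestSteadyStateAndUrine:
    def test_steady_state_arithmetic(self):
        p = point_params()
        assert pk.steady_state_concentration(p, 0.0) == 0.0
        assert pk.steady_state_concentration(p, 0.5) == pytest.approx(
            0.25 * 0.5 / (0.108 * 17.7)
        )
        assert pk.steady_state_concentration(p, 1.0) == pytest.approx(
            2 * pk.steady_state_concentration(p, 0.5)
        )

    def test_urine_arithmetic_and_linearity(self):
        p = point_params(n_creatinine=50.0)
        assert pk.urine_entering_bladder(p, 0.0) == 0.0
        expected = 0.58 * 0.108 * 17.7 * 0.001 / 50.0
        assert pk.urine_entering_bladder(p, 0.001) == pytest.approx(expected)
        assert expected == pytest.approx(2.217e-5, rel=1e-3)
        assert pk.urine_entering_bladder(p, 0.002) == pytest.approx(2 * expected)

    def test_missing_creatinine_errors(self):
        with pytest.raises(ValueError, match="creatinine"):
            pk.urine_entering_bladder(pk.point_estimate_parameters(POINTS), 0.001)


class TestBladderAverage:
    def test_constant_series(self):
        u = np.full(30, 3.3e-7)
        for void in (4, 5, 6):
            assert pk.bladder_average(u, 29, void) == pytest.approx(3.3e-7)

    def test_forced_arithmetic(self):
        u = np.zeros(10)
        u[6:10] = [2e-7, 4e-7, 6e-7, 8e-7]
        assert pk.bladder_average(u, 9, 4) == pytest.approx(5e-7)

    def test_matches_manual_mean(self, rng):
        u = rng.uniform(0, 1e-6, 40)
        assert pk.bladder_average(u, 35, 6) == pytest.approx(u[30:36].mean())

    def test_window_clipped_at_series_start(self):
        u = np.array([1.0, 2.0, 3.0])
        assert pk.bladder_average(u, 1, 6) == pytest.approx(1.5)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="void"):
            pk.bladder_average(np.ones(5), 4, 0)


class TestMassBalance:
    @given(
        seed=st.integers(0, 10_000),
        k=st.floats(0.05, 0.5),
        f=st.floats(0.1, 0.9),
        v=st.floats(5.0, 40.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_excreted_equals_f_times_dose(self, seed, k, f, v):
        rng = np.random.default_rng(seed)
        doses = np.zeros(3000)
        doses[:48] = rng.uniform(0, 0.3, 48)
        excreted = pk.cumulative_excretion(doses, k, f, v, c0=0.0)
        assert excreted == pytest.approx(f * doses.sum(), rel=1e-3)


class TestEndToEnd:
    def test_zero_exposure_prediction_is_floor(self):
        from pkabc import doseplan

        sched = doseplan.build_schedule(
            {
                "participant_id": "X", "body_weight": 70.0,
                "meal_hours_day1": {8, 12, 19}, "collection_hour": 10,
                "fasting_hours": 2.0,
            },
            0.0, 0.0, doseplan.BehaviorDraw(False, 0.0),
        )
        assert pk.predict_urinary_3pba(sched, point_params(), floor=1e-12) == 1e-12

    def test_hand_computed_two_meal_participant(self):
        """Spreadsheet-style hour-by-hour evaluation of one participant."""
        from pkabc import doseplan

        p = point_params(n_creatinine=60.0)
        individual = {
            "participant_id": "X", "body_weight": 50.0,
            "meal_hours_day1": {7, 18}, "collection_hour": 12,
            "fasting_hours": 3.0,
        }
        sched = doseplan.build_schedule(
            individual, 0.002, 0.004, doseplan.BehaviorDraw(False, 0.0)
        )
        got = pk.predict_urinary_3pba(sched, p)

        # manual recursion, mirroring the model definition step by step
        c = 0.25 * (0.15 / 24.0) / (0.108 * 17.7)  # steady state of the mean rate
        series = [c]
        dose_by_hour = {7: 0.05, 18: 0.05, 31: 0.05}
        for t in range(36):
            d = dose_by_hour.get(t, 0.0)
            c = c * np.exp(-0.108) + 0.25 * d / (17.7 * 0.108) * (1 - np.exp(-0.108))
            series.append(c)
        u = [0.58 * 0.108 * 17.7 * ci / 60.0 for ci in series]
        expected = np.mean(u[32:37])  # void window of 5 h ending at hour 36
        assert got == pytest.approx(expected, rel=1e-12)

    def test_standardize_measurement(self):
        assert pk.standardize_measurement(0.39, 100.0) == pytest.approx(3.9e-7)
        assert pk.standardize_measurement(1.0, 1.0) == pytest.approx(1e-4)
        assert pk.standardize_measurement(2.0, 50.0) == pytest.approx(
            2 * pk.standardize_measurement(1.0, 50.0)
        )
        with pytest.raises(ValueError, match="creatinine"):
            pk.standardize_measurement(1.0, 0.0)
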