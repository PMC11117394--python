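"""Dose-schedule construction: equal meal splitting, fasting exclusion,
washing behavior and the steady-state initialization rate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pkabc import doseplan
from pkabc.doseplan import BehaviorDraw

NON_WASHER = BehaviorDraw(is_washer=False, washing_factor=0.0)


class TestSplitDailyDose:
    @pytest.mark.parametrize(
        "dose,meals,expected",
        [
            (0.9, {8, 12, 19}, {8: 0.3, 12: 0.3, 19: 0.3}),
            (0.9, {12}, {12: 0.9}),
            (0.0, {8, 12}, {8: 0.0, 12: 0.0}),
        ],
    )
    def test_equal_division(self, dose, meals, expected):
        out = doseplan.split_daily_dose(dose, meals)
        for h, v in expected.items():
            assert out[h] == pytest.approx(v)
        assert sum(out.values()) == pytest.approx(dose)
        assert all(out[h] == 0 for h in set(range(24)) - meals)

    def test_empty_meals_rejected(self):
        with pytest.raises(ValueError, match="meal"):
            doseplan.split_daily_dose(1.0, set())


class TestCollectionDayMeals:
    @pytest.mark.parametrize(
        "meals,collection,fasting,expected",
        [
            ({8, 12, 19}, 10, 12.0, set()),   # fasting since 22:00 the night before
            ({8, 12, 19}, 10, 0.5, {8}),      # 12 and 19 are not before collection
            ({7, 8}, 10, 2.0, {7}),           # hour 8 sits exactly on the boundary
        ],
    )
    def test_fasting_exclusion(self, meals, collection, fasting, expected):
        assert doseplan.build_collection_day_meals(meals, collection, fasting) == expected

    @given(
        meals=st.sets(st.integers(0, 23), min_size=1, max_size=5),
        collection=st.integers(0, 23),
        fasting=st.floats(0, 24, allow_nan=False),
        extra=st.floats(0, 12, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_longer_fast_never_adds_meals(self, meals, collection, fasting, extra):
        base = doseplan.build_collection_day_meals(meals, collection, fasting)
        longer = doseplan.build_collection_day_meals(meals, collection, fasting + extra)
        assert longer <= base


class TestBehavior:
    def test_degenerate_bernoulli(self, rng):
        draws = [doseplan.sample_behavior(rng, washer_prob=0.0) for _ in range(200)]
        assert not any(d.is_washer for d in draws)

    def test_washer_fraction_and_factor_mean(self, rng):
        n = 100_000
        is_washer, factor = doseplan.sample_behavior_arrays(
            rng, n, doseplan.BehaviorParams()
        )
        # Bernoulli(0.5): 3 s.e. of the washer fraction
        assert abs(is_washer.mean() - 0.5) < 3 * 0.5 / np.sqrt(n)
        # Beta(3, 7): mean 0.30, sd sqrt(0.3*0.7/11)
        se = np.sqrt(0.3 * 0.7 / 11.0) / np.sqrt(n)
        assert abs(factor.mean() - 0.30) < 3 * se

    @pytest.mark.parametrize(
        "behavior,expected",
        [
            (NON_WASHER, 1.0),
            (BehaviorDraw(True, 0.30), 0.70),
            (BehaviorDraw(True, 1.0), 0.0),
        ],
    )
    def test_apply_washing(self, behavior, expected):
        assert doseplan.apply_washing(1.0, behavior) == pytest.approx(expected)

    def test_invalid_params_rejected(self, rng):
        with pytest.raises(Exception, match="washer_prob"):
            doseplan.sample_behavior(rng, washer_prob=1.5)


class TestSteadyStateRate:
    def test_averaging_rule(self):
        assert doseplan.steady_state_initial_rate(0.24, 0.24, 50.0, NON_WASHER) == pytest.approx(0.5)
        assert doseplan.steady_state_initial_rate(0.24, 0.0, 50.0, NON_WASHER) == pytest.approx(0.25)
        assert doseplan.steady_state_initial_rate(0.0, 0.0, 50.0, NON_WASHER) == 0.0

    def test_washing_applies_to_initialization(self):
        washed = doseplan.steady_state_initial_rate(
            0.24, 0.24, 50.0, BehaviorDraw(True, 0.5)
        )
        assert washed == pytest.approx(0.25)


def _individual(meals, collection, fasting, weight=50.0):
    return {
        "participant_id": "X",
        "body_weight": weight,
        "meal_hours_day1": meals,
        "collection_hour": collection,
        "fasting_hours": fasting,
    }


class TestBuildSchedule:
    def test_full_fast_has_empty_day2(self):
        sched = doseplan.build_schedule(
            _individual({8, 12, 19}, 10, 12.0), 0.001, 0.001, NON_WASHER
        )
        assert np.all(sched.doses[24:] == 0)
        assert sched.collection_index == 34

    def test_zero_doses_zero_schedule(self):
        sched = doseplan.build_schedule(
            _individual({8, 12}, 9, 1.0), 0.0, 0.0, NON_WASHER
        )
        assert np.all(sched.doses == 0)
        assert sched.initial_mean_hourly_rate == 0.0

    def test_manual_two_meal_expansion(self):
        # 0.002 mg/kg/day, 50 kg -> 0.1 mg/day split over meals {7, 18};
        # collection at 12:00 with a 3 h fast keeps only the 07:00 meal on day 2.
        sched = doseplan.build_schedule(
            _individual({7, 18}, 12, 3.0), 0.002, 0.004, NON_WASHER
        )
        expected = np.zeros(37)
        expected[7] = 0.05
        expected[18] = 0.05
        expected[24 + 7] = 0.05
        np.testing.assert_allclose(sched.doses, expected)
        # initialization: mean of 0.1 and 0.2 mg/day over 24 h
        assert sched.initial_mean_hourly_rate == pytest.approx(0.15 / 24.0)

    @given(
        dose=st.floats(0, 0.01),
        meals=st.sets(st.integers(0, 23), min_size=1, max_size=5),
        collection=st.integers(0, 23),
        fasting=st.floats(0, 24),
        factor=st.floats(0, 1),
        washer=st.booleans(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_day1_mass_conservation(self, dose, meals, collection, fasting, washer, factor):
        behavior = BehaviorDraw(washer, factor)
        sched = doseplan.build_schedule(
            _individual(meals, collection, fasting), dose, dose, behavior
        )
        adjusted = doseplan.apply_washing(dose * 50.0, behavior)
        assert sched.doses[:24].sum() == pytest.approx(adjusted, rel=1e-9, abs=1e-15)
        assert sched.day1_daily_dose_mg == pytest.approx(adjusted)
        # washing never increases the scheduled mass
        assert adjusted <= dose * 50.0 + 1e-12

    def test_no_dose_at_or_after_collection(self):
        sched = doseplan.build_schedule(
            _individual({8, 12, 19}, 9, 0.0), 0.001, 0.001, NON_WASHER
        )
        assert np.all(sched.doses[sched.collection_index:] == 0)


class TestBulkMatchesScalar:
    def test_matrix_builder_equals_build_schedule(self, rng):
        meals_list = [{7, 12, 18}, {9}, {6, 10, 13, 17, 20}]
        meal_matrix = np.zeros((3, 24), dtype=bool)
        for i, ms in enumerate(meals_list):
            meal_matrix[i, list(ms)] = True
        coll = np.array([10, 15, 8])
        fast = np.array([2.0, 0.0, 11.5])
        weight = np.array([72.0, 51.0, 88.0])
        p_idx = np.array([0, 1, 2, 0])
        d1 = rng.lognormal(-9, 0.5, 4)
        d2 = rng.lognormal(-9, 0.5, 4)
        washer = np.array([True, False, True, False])
        factor = rng.beta(3, 7, 4)

        doses, idx, rate = doseplan.build_schedule_matrix(
            meal_matrix, coll, fast, weight, p_idx, d1, d2, washer, factor
        )
        for row in range(4):
            p = p_idx[row]
            behavior = BehaviorDraw(bool(washer[row]), float(factor[row]))
            sched = doseplan.build_schedule(
                {
                    "participant_id": p,
                    "body_weight": weight[p],
                    "meal_hours_day1": meals_list[p],
                    "collection_hour": coll[p],
                    "fasting_hours": fast[p],
                },
                d1[row], d2[row], behavior,
            )
            np.testing.assert_allclose(doses[row, : len(sched.doses)], sched.doses)
            assert np.all(doses[row, len(sched.doses):] == 0)
            assert idx[row] == sched.collection_index
            assert rate[row] == pytest.approx(sched.initial_mean_hourly_rate)
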