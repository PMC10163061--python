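import datetime
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cotgrow as cg
from cotgrow.meteo import STANDARD_PRESSURE_KPA


class TestEffectiveMeanTemperature:
    @pytest.mark.parametrize(
        "t_max, t_min, expected",
        [
            (30.0, 20.0, 25.0),  # mid-range, no clamping
            (8.0, 4.0, 10.0),  # clamped up to the base temperature
            (48.0, 40.0, 40.0),  # clamped down to the upper limit
            (20.0, 0.0, 10.0),  # mean exactly at the base
        ],
    )
    def test_clamped_mean(self, t_max, t_min, expected):
        assert cg.effective_mean_temperature(t_max, t_min) == expected

    def test_rejects_inverted_extremes(self):
        with pytest.raises(ValueError):
            cg.effective_mean_temperature(10.0, 20.0)

    @given(
        t_min=st.floats(-30, 45),
        spread=st.floats(0, 25),
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_under_reclamping(self, t_min, spread):
        t = cg.effective_mean_temperature(t_min + spread, t_min)
        assert cg.effective_mean_temperature(t, t) == pytest.approx(t)
        assert 10.0 <= t <= 40.0


class TestDailyGdd:
    @pytest.mark.parametrize(
        "t_max, t_min, expected",
        [(30.0, 20.0, 15.0), (8.0, 4.0, 0.0), (48.0, 40.0, 30.0)],
    )
    def test_examples(self, t_max, t_min, expected):
        assert cg.daily_gdd(t_max, t_min) == expected

    @given(t_min=st.floats(-30, 45), spread=st.floats(0, 25))
    @settings(max_examples=50, deadline=None)
    def test_increment_within_activity_window(self, t_min, spread):
        g = cg.daily_gdd(t_min + spread, t_min)
        assert 0.0 <= g <= 30.0


class TestCumulativeGdd:
    def test_constant_increments(self, make_day):
        d0 = datetime.date(2020, 6, 1)
        days = [
            make_day(d0 + datetime.timedelta(days=i), 30.0, 20.0) for i in range(3)
        ]
        acc = cg.cumulative_gdd(days)
        np.testing.assert_allclose(acc.cumulative, [15.0, 30.0, 45.0])

    def test_single_clamped_day(self, make_day):
        acc = cg.cumulative_gdd([make_day(datetime.date(2020, 4, 1), 8.0, 4.0)])
        np.testing.assert_allclose(acc.cumulative, [0.0])

    def test_matches_brute_force_running_sum(self, toy_weather):
        acc = cg.cumulative_gdd(toy_weather)
        expected, total = [], 0.0
        for day in toy_weather:
            t = min(max(0.5 * (day.t_max + day.t_min), 10.0), 40.0)
            total += t - 10.0
            expected.append(total)
        np.testing.assert_allclose(acc.cumulative, expected)

    def test_rejects_empty_and_unordered(self, toy_weather):
        with pytest.raises(ValueError):
            cg.cumulative_gdd([])
        with pytest.raises(ValueError):
            cg.cumulative_gdd(list(reversed(toy_weather)))


class TestSaturationVaporTerms:
    def test_delta_at_freezing(self):
        # hand evaluation: 4098 * 0.6108 / 237.3^2
        atmos = cg.saturation_vapor_terms(0.0)
        assert atmos.delta == pytest.approx(4098.0 * 0.6108 / 237.3**2, rel=1e-12)
        assert atmos.delta == pytest.approx(0.0445, abs=5e-4)

    def test_gamma_at_sea_level(self):
        atmos = cg.saturation_vapor_terms(20.0, 101.3)
        assert atmos.gamma == pytest.approx(0.000665 * 101.3, rel=1e-12)
        assert atmos.gamma == pytest.approx(0.0674, abs=5e-4)

    def test_delta_increases_with_temperature(self):
        temps = np.linspace(0.0, 40.0, 41)
        deltas = [cg.saturation_vapor_terms(t).delta for t in temps]
        assert np.all(np.diff(deltas) > 0)

    def test_out_of_range_temperature_rejected(self):
        with pytest.raises(ValueError):
            cg.saturation_vapor_terms(80.0)


class TestDailyEto:
    def test_zero_numerator_gives_zero(self, make_day):
        day = make_day(
            datetime.date(2020, 7, 1), 28.0, 18.0, e_s=2.0, e_a=2.0, u2=3.0, r_n=5.0, g=5.0
        )
        assert cg.daily_eto(day) == pytest.approx(0.0)

    def test_calm_day_reduces_to_radiation_term(self, make_day):
        day = make_day(datetime.date(2020, 7, 1), 28.0, 18.0, u2=0.0, r_n=12.0)
        atmos = cg.saturation_vapor_terms(day.t_mean)
        expected = 0.408 * atmos.delta * 12.0 / (atmos.delta + atmos.gamma)
        assert cg.daily_eto(day, atmos) == pytest.approx(expected, rel=1e-12)

    def test_against_independent_penman_monteith_evaluation(self, make_day):
        """Cross-check one day against a separately coded FAO-56 evaluation."""
        day = make_day(
            datetime.date(2020, 7, 1), 25.0, 15.0, e_s=2.0, e_a=1.0, u2=2.0, r_n=13.28
        )
        assert day.t_mean == 20.0

        # independent evaluation, term by term
        t = 20.0
        es0 = 0.6108 * math.exp(17.27 * t / (t + 237.3))
        delta = 4098.0 * es0 / (t + 237.3) ** 2
        gamma = 0.000665 * STANDARD_PRESSURE_KPA
        radiation_term = 0.408 * delta * (13.28 - 0.0)
        aero_term = gamma * (900.0 / (t + 273.0)) * 2.0 * 1.0
        oracle = (radiation_term + aero_term) / (delta + gamma * (1.0 + 0.34 * 2.0))

        assert cg.daily_eto(day) == pytest.approx(oracle, abs=1e-6)

    def test_monotone_in_vpd_and_radiation(self, make_day):
        d0 = datetime.date(2020, 7, 1)
        base = make_day(d0, 28.0, 18.0, e_s=3.0, e_a=1.5, u2=2.0, r_n=12.0)
        drier = make_day(d0, 28.0, 18.0, e_s=3.0, e_a=1.0, u2=2.0, r_n=12.0)
        sunnier = make_day(d0, 28.0, 18.0, e_s=3.0, e_a=1.5, u2=2.0, r_n=15.0)
        assert cg.daily_eto(drier) > cg.daily_eto(base)
        assert cg.daily_eto(sunnier) > cg.daily_eto(base)


class TestCumulativeEto:
    def test_identical_days_accumulate_linearly(self, make_day):
        d0 = datetime.date(2020, 7, 1)
        days = [
            make_day(d0 + datetime.timedelta(days=i), 28.0, 18.0) for i in range(3)
        ]
        acc = cg.cumulative_eto(days)
        x = acc.daily[0]
        np.testing.assert_allclose(acc.cumulative, [x, 2 * x, 3 * x])

    def test_radiation_deficit_day_clamped_to_zero(self, make_day):
        day = make_day(
            datetime.date(2020, 7, 1), 20.0, 10.0, e_s=1.5, e_a=1.5, u2=2.0, r_n=1.0, g=3.0
        )
        assert cg.daily_eto(day) < 0  # raw value stays negative
        acc = cg.cumulative_eto([day])
        assert acc.daily[0] == 0.0

    def test_matches_brute_force_clamped_sum(self, toy_weather):
        acc = cg.cumulative_eto(toy_weather)
        expected = np.cumsum(
            [max(cg.daily_eto(d), 0.0) for d in toy_weather]
        )
        np.testing.assert_allclose(acc.cumulative, expected)
        assert np.all(np.diff(acc.cumulative) >= 0)


class TestRelativeAccumulation:
    def test_thirds(self, make_day):
        d0 = datetime.date(2020, 6, 1)
        acc = cg.cumulative_gdd(
            [make_day(d0 + datetime.timedelta(days=i), 30.0, 20.0) for i in range(3)]
        )
        np.testing.assert_allclose(acc.relative, [1 / 3, 2 / 3, 1.0])

    def test_single_day(self, make_day):
        acc = cg.cumulative_gdd([make_day(datetime.date(2020, 6, 1), 30.0, 20.0)])
        np.testing.assert_allclose(acc.relative, [1.0])

    def test_zero_total_rejected(self, make_day):
        acc = cg.cumulative_gdd([make_day(datetime.date(2020, 4, 1), 8.0, 4.0)])
        with pytest.raises(ValueError):
            cg.relative_accumulation(acc)

    def test_invariant_to_uniform_scaling(self, toy_weather):
        acc = cg.cumulative_gdd(toy_weather)
        scaled = cg.AccumSeries(acc.driver_kind, acc.dates, acc.daily * 7.5)
        np.testing.assert_allclose(acc.relative, scaled.relative)
        assert acc.relative.max() == 1.0
        assert acc.relative.min() >= 0.0


class TestWeatherDayValidation:
    def test_invariants_enforced(self):
        d = datetime.date(2020, 7, 1)
        with pytest.raises(ValueError):
            cg.WeatherDay(d, 10.0, 20.0, 2.0, 1.0, 2.0, 12.0)
        with pytest.raises(ValueError):
            cg.WeatherDay(d, 25.0, 15.0, 1.0, 2.0, 2.0, 12.0)  # e_a > e_s
        with pytest.raises(ValueError):
            cg.WeatherDay(d, 25.0, 15.0, 2.0, 1.0, -1.0, 12.0)

    def test_mean_defaults_to_midpoint(self):
        day = cg.WeatherDay(datetime.date(2020, 7, 1), 25.0, 15.0, 2.0, 1.0, 2.0, 12.0)
        assert day.t_mean == 20.0


def test_pressure_at_elevation_decreases():
    p0 = cg.meteo.pressure_at_elevation(0.0)
    p1 = cg.meteo.pressure_at_elevation(1000.0)
    assert p0 == pytest.approx(101.3, rel=1e-6)
    assert p1 < p0
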