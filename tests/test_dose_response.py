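"""Dose-response functions and the temperature-compensation integral."""

import numpy as np
import pandas as pd
import pytest

from phenotherm import (ConfigurationError, DataError, DoseResponseModel,
                        RangeError, TemperatureSeries, compensate_time,
                        eval_response, invert_compensation)


class TestEvalResponse:
    def test_thermal_time_is_identity_above_base(self, wheat_tt):
        assert eval_response(wheat_tt, 10.0) == pytest.approx(10.0)
        assert eval_response(wheat_tt, -3.0) == 0.0

    def test_soybean_base_temperature(self):
        m = DoseResponseModel.thermal_time("soybean")
        assert eval_response(m, 10.0) == pytest.approx(5.0)

    def test_wang_engel_cardinal_values(self, wang_engel):
        m = wang_engel
        assert eval_response(m, m.T_opt) == pytest.approx(m.r_max)
        assert eval_response(m, m.T_min) == 0.0
        assert eval_response(m, m.T_max) == 0.0
        # frozen value computed from the closed form (alpha = 1.23861...)
        assert eval_response(m, 10.0) == pytest.approx(0.6679705, abs=1e-6)

    def test_wang_engel_maximum_at_t_opt(self, wang_engel):
        grid = np.linspace(0.0, 35.0, 3501)
        r = eval_response(wang_engel, grid)
        assert grid[np.argmax(r)] == pytest.approx(wang_engel.T_opt, abs=0.02)
        rising = r[(grid > 0.1) & (grid < 19.9)]
        falling = r[(grid > 20.1) & (grid < 34.9)]
        assert np.all(np.diff(rising) > 0)
        assert np.all(np.diff(falling) < 0)

    def test_asymptotic_limits(self):
        m = DoseResponseModel("asymptotic", T_min=1.0, r_max=1.5, s=-2.0)
        assert eval_response(m, 1.0) == 0.0
        assert eval_response(m, 500.0) == pytest.approx(1.5, rel=1e-6)
        grid = np.linspace(-10, 45, 200)
        assert np.all(eval_response(m, grid) <= 1.5 + 1e-12)

    def test_bilinear_shape(self):
        m = DoseResponseModel("bilinear", T_min=4.0, a=0.3, r_min=0.4)
        # sub-threshold segment rises from 0 to r_min at T_min
        assert eval_response(m, 0.0) == 0.0
        assert eval_response(m, 2.0) == pytest.approx(0.2)
        assert eval_response(m, 4.0) == pytest.approx(0.4)
        assert eval_response(m, 14.0) == pytest.approx(0.4 + 3.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            DoseResponseModel("wang_engel", T_min=25, T_opt=20, T_max=35)
        with pytest.raises(ConfigurationError):
            DoseResponseModel("bilinear", T_min=0.0, a=1.0, r_min=0.1)
        with pytest.raises(ConfigurationError):
            DoseResponseModel("asymptotic", r_max=0.0)
        with pytest.raises(ConfigurationError):
            DoseResponseModel("no_such_kind")

    def test_bilinear_kink_warns(self):
        with pytest.warns(UserWarning, match="kink"):
            DoseResponseModel("bilinear", T_min=5.0, a=0.01, r_min=0.4)

    def test_nan_temperature_rejected(self, wheat_tt):
        with pytest.raises(DataError):
            eval_response(wheat_tt, np.nan)

    def test_plain_callable_is_clipped(self):
        assert eval_response(lambda T: np.asarray(T) - 100.0, 10.0) == 0.0


class TestTemperatureSeries:
    def test_rejects_disorder_and_nan(self):
        ts = pd.DatetimeIndex(["2020-01-01 02:00", "2020-01-01 01:00"])
        with pytest.raises(DataError):
            TemperatureSeries(ts, [1.0, 2.0])
        good = pd.date_range("2020-01-01", periods=3, freq="h")
        with pytest.raises(DataError):
            TemperatureSeries(good, [1.0, np.nan, 2.0])
        with pytest.raises(DataError):
            TemperatureSeries(good[:1], [1.0])

    def test_gap_check(self):
        ts = pd.DatetimeIndex(["2020-01-01 00:00", "2020-01-01 01:00",
                               "2020-01-01 09:00"])
        s = TemperatureSeries(ts, [5.0, 6.0, 7.0])
        with pytest.raises(DataError, match="gap"):
            s.check_gaps(3.0)
        s.check_gaps(10.0)


class TestCompensation:
    def test_constant_temperature_degree_days(self, wheat_tt, constant_temps):
        comp = compensate_time(wheat_tt, constant_temps)
        assert comp.total == pytest.approx(30.0)  # (15-0) degC * 2 d

    def test_below_base_accumulates_nothing(self, constant_temps):
        m = DoseResponseModel("linear", T_min=20.0, a=1.0)
        comp = compensate_time(m, constant_temps)
        assert np.all(comp.cumulative == 0.0)

    def test_matches_fine_trapezoid_on_diurnal_course(self):
        # brute-force oracle: 1-minute trapezoid quadrature of the
        # continuous temperature function
        m = DoseResponseModel("asymptotic", T_min=1.0, r_max=1.0, s=-2.0)
        f = lambda h: 12 + 8 * np.sin(2 * np.pi * (h - 9) / 24)
        hours = np.arange(0, 120 + 1)
        ts = pd.date_range("2020-04-01", periods=len(hours), freq="h")
        step = compensate_time(m, TemperatureSeries(ts, f(hours))).total
        fine = np.arange(0, 120 + 1 / 60, 1 / 60)
        oracle = np.trapezoid(np.maximum(
            m.r_max * (1 - np.exp(-np.exp(m.s) * (f(fine) - m.T_min))), 0),
            fine) / 24.0
        assert step == pytest.approx(oracle, rel=0.005)

    def test_additive_over_adjacent_intervals(self, diurnal_temps, wheat_tt):
        ts = diurnal_temps.timestamps
        mid = ts[100]
        full = compensate_time(wheat_tt, diurnal_temps).at(ts[200])
        part1 = compensate_time(wheat_tt, diurnal_temps).at(mid)
        part2 = compensate_time(wheat_tt, diurnal_temps, mid).at(ts[200])
        assert part1 + part2 == pytest.approx(full, abs=1e-9)

    def test_thermal_time_equals_independent_gdd_sum(self, diurnal_temps,
                                                     wheat_tt):
        # classic growing-degree computation: hourly max(T-Tb,0)/24
        gdd = np.maximum(diurnal_temps.values[:-1], 0).sum() / 24.0
        comp = compensate_time(wheat_tt, diurnal_temps)
        assert comp.total == pytest.approx(gdd)

    def test_t0_outside_span_rejected(self, constant_temps, wheat_tt):
        with pytest.raises(RangeError):
            compensate_time(wheat_tt, constant_temps,
                            t0=pd.Timestamp("2019-12-01"))


class TestInvertCompensation:
    def test_zero_target_returns_start(self, constant_temps, wheat_tt):
        t1 = constant_temps.timestamps[3]
        assert invert_compensation(wheat_tt, constant_temps, t1, 0.0) == t1

    def test_constant_temperature_inverse(self, constant_temps, wheat_tt):
        t1 = constant_temps.timestamps[0]
        t2 = invert_compensation(wheat_tt, constant_temps, t1, 30.0)
        assert t2 == t1 + pd.Timedelta(hours=48)

    def test_round_trip_random_courses(self, wheat_tt):
        rng = np.random.default_rng(42)
        ts = pd.date_range("2020-04-01", periods=400, freq="h")
        for _ in range(10):
            temps = TemperatureSeries(ts, rng.uniform(2, 25, len(ts)))
            t1, t2 = ts[5], ts[300]
            y = compensate_time(wheat_tt, temps, t1).at(t2)
            back = invert_compensation(wheat_tt, temps, t1, y)
            assert abs(back - t2) <= pd.Timedelta(hours=1)

    def test_unreachable_target(self, constant_temps, wheat_tt):
        with pytest.raises(RangeError):
            invert_compensation(wheat_tt, constant_temps,
                                constant_temps.timestamps[0], 1e6)
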