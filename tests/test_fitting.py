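"""Maximum-likelihood response fitting from tracker and sparse trait data."""

import numpy as np
import pandas as pd
import pytest

from phenotherm import (DataError, DoseResponseModel, GrowthSeries,
                        IdentifiabilityError, TemperatureSeries, compute_rgr,
                        correct_leaf_weight, eval_response, fit_increment_ml,
                        fit_tracker_ml, smooth_series)
from phenotherm.fitting import _ar_acovf_unit, _ar_profile_loglik, _pacf_to_ar


class TestComputeRgr:
    def test_flat_and_e_fold(self):
        ts = pd.date_range("2020-06-01", periods=2, freq="h")
        r, _ = compute_rgr([100.0, 100.0], ts)
        assert r[0] == 0.0
        r, _ = compute_rgr([100.0, 100.0 * np.e], ts)
        assert r[0] == pytest.approx(1.0)

    def test_exponential_growth_gives_constant_rate(self):
        rng = np.random.default_rng(0)
        hours = np.sort(rng.uniform(0, 100, 30))
        ts = pd.DatetimeIndex(pd.Timestamp("2020-06-01")
                              + pd.to_timedelta(hours, unit="h"))
        k = 0.07
        areas = 50.0 * np.exp(k * hours)
        r, _ = compute_rgr(areas, ts)
        assert np.allclose(r, k)

    def test_nonpositive_area_rejected(self):
        ts = pd.date_range("2020-06-01", periods=2, freq="h")
        with pytest.raises(DataError):
            compute_rgr([100.0, 0.0], ts)


class TestLeafWeightCorrection:
    def test_zero_coefficient_is_identity(self):
        rates = np.array([1.0, 2.0, 3.0])
        temps = np.array([5.0, 10.0, 15.0])
        assert np.array_equal(correct_leaf_weight(rates, temps, 0.0), rates)

    def test_magnitude_per_degree(self):
        # 0.004 mm/h per degC applied linearly around the reference
        rates = np.zeros(2)
        temps = np.array([10.0, 20.0])
        out = correct_leaf_weight(rates, temps, 0.004, reference=10.0)
        assert out[1] == pytest.approx(-0.04)
        assert out[0] == 0.0

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        rates = rng.normal(1.0, 0.3, 50)
        temps = rng.uniform(2, 25, 50)
        corr = correct_leaf_weight(rates, temps)
        back = correct_leaf_weight(corr, temps, undo=True)
        assert np.allclose(back, rates)

    def test_misaligned_rejected(self):
        with pytest.raises(DataError):
            correct_leaf_weight(np.zeros(3), np.zeros(4))


class TestArLikelihood:
    def test_acovf_matches_statsmodels(self):
        from statsmodels.tsa.arima_process import arma_acovf
        for phi in ([0.6], [0.6, -0.2], [0.5, 0.2, -0.1]):
            mine = _ar_acovf_unit(np.array(phi))
            ref = arma_acovf(np.r_[1, -np.array(phi)], [1],
                             nobs=len(phi), sigma2=1.0)
            assert np.allclose(mine, ref)

    def test_pacf_transform_is_stationary(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pacf = np.tanh(rng.normal(0, 2, 3))
            phi = _pacf_to_ar(pacf)
            # roots of 1 - phi_1 z - ... - phi_p z^p outside the unit circle
            roots = np.roots(np.r_[1, -phi][::-1])
            assert np.all(np.abs(roots) > 1.0)

    def test_white_noise_loglik_matches_closed_form(self):
        rng = np.random.default_rng(4)
        e = rng.normal(0, 2.0, 500)
        ll, sigma = _ar_profile_loglik([e], np.empty(0))
        s2 = np.mean(e**2)
        expect = -0.5 * (500 * np.log(2 * np.pi * s2) + 500)
        assert ll == pytest.approx(expect)
        assert sigma == pytest.approx(np.sqrt(s2))


def _simulate_tracker(seed, n=2000, phi=0.6, sigma=0.2,
                      model=None):
    rng = np.random.default_rng(seed)
    model = model or DoseResponseModel("asymptotic", T_min=1.0, r_max=1.5,
                                       s=-2.0)
    T = 10 + 8 * np.sin(np.linspace(0, 30 * np.pi, n)) + rng.normal(0, 2, n)
    e = np.zeros(n)
    innov = rng.normal(0, sigma, n)
    for t in range(n):
        e[t] = innov[t] + (phi * e[t - 1] if t else 0.0)
    y = eval_response(model, T) + e
    return pd.DataFrame({"cultivar": "c1", "series_id": "s1",
                         "temp": T, "rate": y})


class TestTrackerFit:
    def test_recovers_asymptotic_with_ar1_noise(self):
        df = _simulate_tracker(seed=42, n=5000)
        fit = fit_tracker_ml(df, "asymptotic", level="species")
        assert abs(fit.model.T_min - 1.0) < 0.5
        assert abs(fit.model.r_max - 1.5) / 1.5 < 0.05
        assert fit.ar_order == 1
        assert abs(fit.ar_coefficients[0] - 0.6) < 0.1
        assert fit.bic == pytest.approx(
            -2 * fit.log_likelihood + (3 + 1 + 1) * np.log(fit.n_obs))

    def test_noise_free_linear_exact_and_iid_selected(self):
        rng = np.random.default_rng(7)
        T = rng.uniform(0, 25, 300)
        df = pd.DataFrame({"cultivar": "c1", "series_id": "s1", "temp": T,
                           "rate": np.maximum(T - 0.0, 0.0)})
        fit = fit_tracker_ml(df, "linear", level="species")
        assert fit.model.T_min == pytest.approx(0.0, abs=0.01)
        assert fit.model.a == pytest.approx(1.0, rel=1e-3)
        assert fit.ar_order == 0

    def test_constant_temperature_unidentifiable(self):
        df = pd.DataFrame({"cultivar": "c1", "series_id": "s1",
                           "temp": np.full(100, 15.0),
                           "rate": np.ones(100)})
        with pytest.raises(IdentifiabilityError):
            fit_tracker_ml(df, "linear", level="species")

    def test_too_few_observations(self):
        df = _simulate_tracker(seed=1, n=30)
        with pytest.raises(DataError):
            fit_tracker_ml(df, "asymptotic", level="species")

    def test_cultivar_level_returns_per_cultivar_fits(self):
        a = _simulate_tracker(seed=1, n=400)
        b = _simulate_tracker(seed=2, n=400)
        b["cultivar"] = "c2"
        b["series_id"] = "s2"
        fits = fit_tracker_ml(pd.concat([a, b]), "linear", level="cultivar")
        assert set(fits) == {"c1", "c2"}
        assert all(f.model.level == "cultivar" for f in fits.values())

    def test_determinism(self):
        df = _simulate_tracker(seed=9, n=800)
        f1 = fit_tracker_ml(df, "asymptotic", level="species")
        f2 = fit_tracker_ml(df.copy(), "asymptotic", level="species")
        assert f1.model.to_dict() == f2.model.to_dict()
        assert f1.bic == f2.bic


def _integrated_series(model, temps, dates, scale, noise, rng, cid="c1",
                       year=2020, rep="r1"):
    from phenotherm import compensate_time
    comp = compensate_time(model, temps)
    latent = np.array([comp.at(d) for d in dates]) * scale
    return GrowthSeries(cid, year, rep, "height", dates,
                        latent + rng.normal(0, noise, len(dates)))


class TestIncrementFit:
    def test_noise_free_linear_recovered(self):
        rng = np.random.default_rng(0)
        ts = pd.date_range("2020-04-01", periods=24 * 50, freq="h")
        temps = TemperatureSeries(
            ts, 12 + 7 * np.sin(2 * np.pi * np.arange(len(ts)) / 24)
            + rng.normal(0, 2, len(ts)))
        true = DoseResponseModel("linear", T_min=3.0, a=0.8)
        dates = ts[24 * 2::24 * 5][:10]
        series = [_integrated_series(true, temps, pd.DatetimeIndex(dates),
                                     1.0, 0.0, rng, rep=f"r{k}")
                  for k in range(2)]
        fit = fit_increment_ml(series, temps, "linear")
        assert fit.model.T_min == pytest.approx(3.0, abs=0.15)
        assert fit.model.a == pytest.approx(0.8, rel=0.02)

    def test_two_measurements_rejected(self):
        ts = pd.date_range("2020-04-01", periods=48, freq="h")
        temps = TemperatureSeries(ts, np.full(48, 15.0))
        s = GrowthSeries("c1", 2020, "r1", "height", ts[[0, 47]], [0.0, 1.0])
        with pytest.raises(DataError):
            fit_increment_ml([s], temps, "linear")


class TestSmoothSeries:
    def _series(self, values, n=None):
        n = n or len(values)
        ts = pd.date_range("2020-04-01", periods=n, freq="D")
        return GrowthSeries("c1", 2020, "r1", "height", ts, values)

    def test_monotone_line_unchanged(self):
        y = np.linspace(0, 100, 15)
        out = smooth_series(self._series(y))
        assert np.allclose(out.values, y, atol=0.5)

    def test_output_monotone_under_noise(self):
        rng = np.random.default_rng(5)
        y = np.linspace(0, 300, 25) + rng.normal(0, 15, 25)
        out = smooth_series(self._series(y))
        assert np.all(np.diff(out.values) >= -1e-8)

    def test_noise_reduction(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 1, 40)
        truth = 400 / (1 + np.exp(-8 * (t - 0.5)))
        noisy = truth + rng.normal(0, 20, 40)
        out = smooth_series(self._series(noisy))
        rmse = np.sqrt(np.mean((out.values - truth) ** 2))
        assert rmse < 20.0

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            smooth_series(self._series(np.array([1.0, 2.0, 3.0])))
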