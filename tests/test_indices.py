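"""Environmental stress indices and the lasso residual attribution."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist, norm

from phenotherm import (DataError, build_index_table, cold_stress_index,
                        extreme_indices, lasso_residuals, spei, spi,
                        thornthwaite_pet)
from phenotherm.indices import validate_weather


def _climate(seed=5, years=10):
    rng = np.random.default_rng(seed)
    days = pd.date_range("2000-01-01", periods=365 * years, freq="D")
    wet = rng.random(len(days)) < 0.45
    precip = pd.Series(np.where(wet, rng.gamma(2, 5, len(days)), 0.0),
                       index=days)
    t_mean = pd.Series(
        10 + 9 * np.sin(2 * np.pi * (days.dayofyear - 110) / 365)
        + rng.normal(0, 2, len(days)), index=days)
    return days, precip, t_mean


class TestThornthwaite:
    def test_frozen_month_gives_zero(self):
        days = pd.date_range("2000-01-01", periods=365 * 2, freq="D")
        t = pd.Series(np.where(days.month.isin([1, 2]), -5.0, 12.0),
                      index=days)
        pet = thornthwaite_pet(t, 47.0)
        assert (pet[days.month == 1] == 0).all()
        assert (pet[days.month == 7] > 0).all()

    def test_matches_textbook_formula_constant_climate(self):
        # independent closed-form computation for a constant 10 degC year
        days = pd.date_range("2001-01-01", "2002-12-31", freq="D")
        t = pd.Series(10.0, index=days)
        pet = thornthwaite_pet(t, 47.0)
        I = 12 * (10.0 / 5) ** 1.514
        a = (6.75e-7 * I**3 - 7.71e-5 * I**2 + 1.792e-2 * I + 0.49239)
        july = pet[(days.year == 2001) & (days.month == 7)]
        doy = np.arange(182, 213)
        decl = 0.409 * np.sin(2 * np.pi / 365 * doy - 1.39)
        L = (24 / np.pi * np.arccos(np.clip(
            -np.tan(np.deg2rad(47.0)) * np.tan(decl), -1, 1))).mean()
        expect = 16 * (L / 12) * (31 / 30) * (10 * 10.0 / I) ** a / 31
        assert july.iloc[0] == pytest.approx(expect, rel=0.01)

    def test_monotone_in_temperature(self):
        days = pd.date_range("2000-01-01", periods=730, freq="D")
        base = pd.Series(10.0, index=days)
        warm = base.copy()
        warm[days.month == 6] = 14.0
        p0 = thornthwaite_pet(base, 47.0)
        p1 = thornthwaite_pet(warm, 47.0)
        assert p1[days.month == 6].sum() > p0[days.month == 6].sum()

    def test_needs_a_year_of_data(self):
        days = pd.date_range("2000-01-01", periods=60, freq="D")
        with pytest.raises(DataError):
            thornthwaite_pet(pd.Series(10.0, index=days), 47.0)


class TestSpi:
    def test_calibration_mean_zero_sd_one(self):
        _, precip, _ = _climate(years=50)
        s = spi(precip)
        assert abs(s.mean()) < 0.1
        assert 0.85 < s.std() < 1.15

    def test_fitted_median_maps_to_exact_zero(self):
        _, precip, _ = _climate(years=10)
        s, fit = spi(precip, return_fit=True)
        med = gamma_dist.ppf((0.5 - fit["q"]) / (1 - fit["q"]),
                             fit["shape"], scale=fit["scale"])
        prob = fit["q"] + (1 - fit["q"]) * gamma_dist.cdf(
            med, fit["shape"], scale=fit["scale"])
        assert norm.ppf(prob) == pytest.approx(0.0, abs=1e-12)

    def test_tail_probability_matches_normal(self):
        _, precip, _ = _climate(years=50)
        s = spi(precip)
        assert np.mean(s > 1.0) == pytest.approx(norm.sf(1.0), abs=0.03)

    def test_unit_rescaling_invariance(self):
        _, precip, _ = _climate(years=10)
        a = spi(precip)
        b = spi(precip / 10.0)  # mm -> cm
        assert np.max(np.abs((a - b).to_numpy())) < 1e-6

    def test_sign_flip_option(self):
        _, precip, _ = _climate(years=5)
        assert np.allclose(spi(precip).to_numpy(),
                           -spi(precip, sign_flip=True).to_numpy())

    def test_short_record_rejected(self):
        _, precip, _ = _climate(years=1)
        with pytest.raises(DataError):
            spi(precip.iloc[:300])


class TestSpei:
    def test_calibration(self):
        days, precip, t_mean = _climate(years=50)
        pet = thornthwaite_pet(t_mean, 47.45)
        s = spei(precip, pet)
        assert abs(s.mean()) < 0.1
        assert 0.85 < s.std() < 1.15

    def test_zero_pet_preserves_spi_ranks(self):
        days, precip, _ = _climate(years=10)
        pet = pd.Series(0.0, index=days)
        a = spi(precip).to_numpy()
        b = spei(precip, pet).to_numpy()
        from scipy.stats import spearmanr
        # same ordering up to ties (tied zero-precipitation windows)
        assert spearmanr(a, b).statistic > 0.9999

    def test_shift_invariance(self):
        days, precip, t_mean = _climate(years=10)
        pet = thornthwaite_pet(t_mean, 47.45)
        a = spei(precip, pet)
        b = spei(precip + 2.0, pet)  # constant water-balance shift
        assert np.max(np.abs((a - b).to_numpy())) < 1e-8


class TestPeriodIndices:
    def test_cold_stress_direct_sum(self):
        days = pd.date_range("2020-01-01", periods=3, freq="D")
        t_min = pd.Series([-2.0, 1.0, -3.0], index=days)
        assert cold_stress_index(t_min, days[0], days[-1]
                                 + pd.Timedelta(days=1)) == 5.0

    def test_cold_stress_additive(self):
        rng = np.random.default_rng(0)
        days = pd.date_range("2020-01-01", periods=60, freq="D")
        t_min = pd.Series(rng.normal(0, 4, 60), index=days)
        whole = cold_stress_index(t_min, days[0], days[59])
        split = (cold_stress_index(t_min, days[0], days[30])
                 + cold_stress_index(t_min, days[30], days[59]))
        assert whole == pytest.approx(split)

    def test_extreme_sums_stated_convention(self):
        days = pd.date_range("2020-01-01", periods=3, freq="D")
        s = pd.Series([1.5, 0.5, -2.0], index=days)
        out = extreme_indices(s, days[0], days[-1] + pd.Timedelta(days=1))
        assert out["above_1"] == 1.5
        assert out["below_1"] == -2.0
        assert out["above_1p75"] == 0.0
        assert out["below_1p75"] == -2.0

    def test_extreme_subset_magnitude(self):
        rng = np.random.default_rng(1)
        days = pd.date_range("2020-01-01", periods=200, freq="D")
        s = pd.Series(rng.normal(0, 1.3, 200), index=days)
        out = extreme_indices(s, days[0], days[-1])
        assert abs(out["below_1p75"]) <= abs(out["below_1"])
        assert out["above_1p75"] <= out["above_1"]


class TestIndexTable:
    def _weather(self, years=3):
        days, precip, t_mean = _climate(seed=2, years=years)
        return pd.DataFrame({
            "date": days, "t_mean": t_mean, "t_min": t_mean - 4,
            "t_max": t_mean + 4, "precip_mm": precip,
            "radiation": 15 + 8 * np.sin(2 * np.pi * days.dayofyear / 365),
        }).reset_index(drop=True)

    def test_row_count_and_columns(self):
        w = self._weather()
        periods = {2001: {"vegetative": ("2001-03-01", "2001-05-01"),
                          "generative": ("2001-05-01", "2001-06-10")},
                   2002: {"vegetative": ("2002-03-01", "2002-05-01"),
                          "generative": ("2002-05-01", "2002-06-10")}}
        tab = build_index_table(w, periods)
        assert len(tab) == 4
        assert {"spi_min", "spei_max", "t_mean_cum", "cold_stress",
                "spi_above_1", "spei_below_1p75"} <= set(tab.columns)
        assert not tab.isna().any().any()

    def test_invalid_weather_schema(self):
        w = self._weather().drop(columns=["t_min"])
        with pytest.raises(DataError, match="t_min"):
            validate_weather(w)

    def test_temperature_ordering_enforced(self):
        w = self._weather()
        w.loc[3, "t_min"] = w.loc[3, "t_max"] + 5
        with pytest.raises(DataError):
            validate_weather(w)


class TestLasso:
    def _planted(self, seed, n=72, sigma=0.15):
        rng = np.random.default_rng(seed + 100)
        X = pd.DataFrame(rng.normal(0, 1, (n, 20)),
                         columns=[f"f{i}" for i in range(20)])
        y = 2 * X["f3"] - 1 * X["f11"] + rng.normal(0, sigma, n)
        return X, y

    def test_huge_lambda_all_zero(self):
        X, y = self._planted(0)
        att = lasso_residuals(y, X, seed=0, lambdas=[1e6])
        assert (att.coefficients == 0).all()

    def test_lambda_zero_matches_ols(self):
        import statsmodels.api as sm
        X, y = self._planted(1)
        att = lasso_residuals(y, X, seed=1, lambdas=[1e-8])
        Xs = (X - X.mean()) / X.std(ddof=0)
        ols = sm.OLS(y, sm.add_constant(Xs)).fit()
        assert np.max(np.abs(att.coefficients.to_numpy()
                             - ols.params.iloc[1:].to_numpy())) < 1e-4

    def test_selected_support_with_1se_rule(self):
        X, y = self._planted(2)
        att = lasso_residuals(y, X, seed=2, rule="1se")
        assert set(att.selected.index) == {"f3", "f11"}
        assert np.sign(att.selected["f3"]) > 0 > np.sign(att.selected["f11"])

    def test_constant_residuals_null_model(self):
        X, _ = self._planted(3)
        att = lasso_residuals(np.full(len(X), 2.5), X, seed=3)
        assert (att.coefficients == 0).all()
        assert att.intercept == pytest.approx(2.5)

    def test_reproducible_given_seed(self):
        X, y = self._planted(4)
        a = lasso_residuals(y, X, seed=9)
        b = lasso_residuals(y, X, seed=9)
        assert a.lambda_ == b.lambda_
        assert np.array_equal(a.coefficients, b.coefficients)
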