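"""Phenology linearization, G×E decomposition, and jointing estimation."""

import numpy as np
import pandas as pd
import pytest

from phenotherm import (DataError, DoseResponseModel, GrowthSeries,
                        TemperatureSeries, estimate_jointing_qmer,
                        fit_gxe_model, linearize_period, scale_per_genotype)
from phenotherm.phenology import normalize_durations, rate_unit


@pytest.fixture
def const10_year():
    ts = pd.date_range("2020-03-01", periods=24 * 120, freq="h")
    return TemperatureSeries(ts, np.full(len(ts), 10.0))


class TestLinearizePeriod:
    def test_constant_temperature_degree_days(self, wheat_tt, const10_year):
        y = linearize_period(wheat_tt, const10_year, "2020-03-10",
                             "2020-03-30")
        assert y == pytest.approx(200.0)  # 10 degC x 20 d

    def test_below_base_gives_zero(self, const10_year):
        m = DoseResponseModel("linear", T_min=15.0, a=1.0)
        assert linearize_period(m, const10_year, "2020-03-10",
                                "2020-03-30") == 0.0

    def test_round_trip_with_generator(self, small_scenario):
        # re-linearizing under the generating model returns the generating
        # threshold (zero-jitter scenario)
        from phenotherm import ScenarioConfig, generate_scenario
        cfg = ScenarioConfig(seed=21, n_cultivars=3, n_years=2,
                             jitter_days=0.0)
        sc = generate_scenario(cfg)
        per = sc.periods[sc.periods.stage_pair == "vegetative"]
        for row in per.itertuples(index=False):
            m = sc.cultivars[row.cultivar]
            y = linearize_period(m, sc.air_by_year[row.year], row.t1, row.t2)
            thr = sc.thresholds.loc[row.cultivar, "jointing"]
            assert y == pytest.approx(thr, rel=1e-3)

    def test_coverage_gap_rejected(self, wheat_tt, const10_year):
        with pytest.raises(DataError):
            linearize_period(wheat_tt, const10_year, "2020-02-01",
                             "2020-03-10")


class TestScaling:
    def _frame(self, y):
        return pd.DataFrame({"cultivar": ["a"] * len(y), "year": 2020,
                             "rep": "r1", "stage_pair": "vegetative",
                             "t1": pd.Timestamp("2020-03-01"),
                             "t2": pd.Timestamp("2020-04-01"), "y": y})

    def test_mean_one_per_genotype(self):
        out = scale_per_genotype(self._frame([2.0, 4.0]))
        assert list(out["y_scaled"]) == [pytest.approx(2 / 3),
                                         pytest.approx(4 / 3)]

    def test_idempotent(self):
        once = scale_per_genotype(self._frame([2.0, 4.0]))
        twice = scale_per_genotype(once.assign(y=once["y_scaled"]))
        assert np.allclose(once["y_scaled"], twice["y_scaled"])

    def test_zero_mean_rejected(self):
        with pytest.raises(DataError):
            scale_per_genotype(self._frame([0.0, 0.0]))

    def test_rate_unit_removes_intrinsic_scale(self):
        a = DoseResponseModel("asymptotic", T_min=1.0, r_max=1.0, s=-2.0)
        b = DoseResponseModel("asymptotic", T_min=1.0, r_max=2.0, s=-2.0)
        assert rate_unit(b) == pytest.approx(2 * rate_unit(a))
        df = pd.concat([self._frame([10.0]).assign(cultivar="a"),
                        self._frame([20.0]).assign(cultivar="b")])
        out, div = normalize_durations(df, {"a": a, "b": b})
        # same development, double intrinsic rate: same normalized duration
        assert out["y_scaled"].iloc[0] == pytest.approx(
            out["y_scaled"].iloc[1])


def _planted_periods(seed, g_sd, vg_sd, e_sd, n_geno=12, n_year=6, n_rep=2):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, g_sd, n_geno)
    v = rng.normal(0, 0.04, n_year)
    vg = rng.normal(0, vg_sd, (n_geno, n_year))
    rows = []
    for i in range(n_geno):
        for j in range(n_year):
            for k in range(n_rep):
                rows.append({
                    "cultivar": f"c{i:02d}", "year": 2015 + j,
                    "rep": f"r{k}", "stage_pair": "vegetative",
                    "t1": pd.Timestamp("2015-03-01"),
                    "t2": pd.Timestamp("2015-05-01"),
                    "y_scaled": 1 + g[i] + v[j] + vg[i, j]
                                + rng.normal(0, e_sd)})
    return pd.DataFrame(rows)


class TestGxEModel:
    def test_null_interaction(self):
        pcts, spmins = [], []
        for seed in range(5):
            df = _planted_periods(seed, g_sd=0.06, vg_sd=0.0, e_sd=0.02)
            d = fit_gxe_model(df)
            pcts.append(d.pct_gxe)
            spmins.append(d.spearman_by_year.min())
        assert np.median(pcts) < 10
        assert np.median(spmins) >= 0.9

    def test_planted_two_to_one_variance_ratio(self):
        # interaction variance = 2 x genotype variance -> expect ~66.7%
        pcts = []
        for seed in range(20):
            df = _planted_periods(seed, g_sd=0.05,
                                  vg_sd=0.05 * np.sqrt(2), e_sd=0.02)
            pcts.append(fit_gxe_model(df).pct_gxe)
        assert 55 < np.median(pcts) < 80

    def test_one_year_rejected(self):
        df = _planted_periods(0, 0.05, 0.0, 0.02, n_year=1)
        with pytest.raises(DataError):
            fit_gxe_model(df)

    def test_spearman_one_without_interaction_blups(self):
        df = _planted_periods(3, g_sd=0.08, vg_sd=0.0, e_sd=0.005)
        d = fit_gxe_model(df)
        if d.boundary_flags.get("vg", False):
            assert np.all(d.spearman_by_year == 1.0)

    def test_pct_invariant_to_genotype_rescaling(self):
        df = _planted_periods(4, g_sd=0.05, vg_sd=0.05, e_sd=0.02)
        df = df.rename(columns={"y_scaled": "y"})
        scaled = scale_per_genotype(df)
        df2 = df.copy()
        df2.loc[df2["cultivar"] == "c03", "y"] *= 7.5
        scaled2 = scale_per_genotype(df2)
        a = fit_gxe_model(scaled).pct_gxe
        b = fit_gxe_model(scaled2).pct_gxe
        assert a == pytest.approx(b, abs=0.01)  # REML optimizer tolerance

    def test_noise_drives_pct_down_under_true_model(self):
        # y constant per genotype up to noise: interaction tends to 0
        pct_by_noise = []
        for e_sd in (0.05, 0.01, 0.001):
            pcts = [fit_gxe_model(_planted_periods(s, g_sd=0.08, vg_sd=0.0,
                                                   e_sd=e_sd)).pct_gxe
                    for s in range(3)]
            pct_by_noise.append(np.median(pcts))
        assert pct_by_noise[-1] <= 10.0
        assert max(pct_by_noise) <= 25.0


class TestQmer:
    def _height(self, values, freq="D"):
        ts = pd.date_range("2020-04-01", periods=len(values), freq=freq)
        return GrowthSeries("c1", 2020, "r1", "height", ts, values)

    def test_logistic_curve_matches_dense_scan(self):
        t = np.linspace(0, 60, 61)
        h = 600 / (1 + np.exp(-0.15 * (t - 35)))
        date, flag = estimate_jointing_qmer(self._height(h))
        assert flag == "ok"
        # brute-force scan on a dense grid of the analytic rate
        td = np.linspace(0, 60, 60001)
        rate = (600 * 0.15 * np.exp(-0.15 * (td - 35))
                / (1 + np.exp(-0.15 * (td - 35))) ** 2)
        t_star = td[np.argmax(rate >= 0.25 * rate.max())]
        expect = pd.Timestamp("2020-04-01") + pd.Timedelta(days=t_star)
        assert abs(date - expect) < pd.Timedelta(days=1.5)
        inflection = pd.Timestamp("2020-04-01") + pd.Timedelta(days=35)
        assert date < inflection

    def test_linear_height_degenerate(self):
        date, flag = estimate_jointing_qmer(self._height(
            np.linspace(0, 100, 20)))
        assert flag == "degenerate"
        assert date == pd.Timestamp("2020-04-01")

    def test_flat_series_rejected(self):
        with pytest.raises(DataError):
            estimate_jointing_qmer(self._height(np.full(10, 5.0)))
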