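"""Synthetic field-phenotyping scenarios.

Generates every input the pipeline consumes — hourly air/soil temperature,
daily weather, cultivar-specific response parameters, dense tracker rate
series, sparse trait series and phenology stage dates — with the
statistical structure the analysis assumes:

* weather: annual + diurnal sinusoids with AR(1) hourly noise and a random
  year offset; soil temperature as an exponentially smoothed, damped and
  lagged copy of air temperature; daily precipitation as Bernoulli
  occurrence × gamma amounts; global radiation as a clear-sky seasonal
  curve shaded on wet days;
* cultivars: parameters drawn around species means — either "intrinsic
  only" (only the maximum rate r_max varies: a shared response shape scaled
  per cultivar) or "per se" (cardinal temperatures / steepness vary too);
* tracker rates: response(T) + AR(p) measurement noise at minutes-to-hourly
  cadence;
* trait series: noisy sparse observations of the scaled compensation
  integral (canopy cover capped at 100%);
* phenology: each stage date is the instant the genotype's own compensated
  time crosses a genotype-fixed threshold (chained stages, optional ±1 day
  observation jitter) — the premise that temperature drives development.

Default scenario dimensions mirror a multi-year single-site field
experiment: wheat 12 cultivars × 6 years × 2 replications, soybean
3 × 4 × 3.  All randomness flows from one seed through named substreams,
so a configuration regenerates byte-identical data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dose_response import (DoseResponseModel, TemperatureSeries,
                            compensate_time, invert_compensation)
from .errors import ConfigurationError, RangeError
from .fitting import GrowthSeries

__all__ = ["ScenarioConfig", "Scenario", "gen_weather", "gen_cultivars",
           "gen_tracker_series", "gen_trait_series", "gen_phenology",
           "generate_scenario"]


def _stream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Named, reproducible random substream."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key, *extra]))


@dataclass
class ScenarioConfig:
    """Study conditions of a synthetic multi-year field experiment."""

    crop: str = "wheat"
    n_cultivars: int = 12
    n_years: int = 6
    n_reps: int = 2
    start_year: int = 2015
    seed: int = 1

    # cultivar response distribution
    response_kind: str = "asymptotic"
    species_params: dict = field(default_factory=dict)
    cultivar_sd: dict = field(default_factory=dict)
    mode: str = "per_se"            # per_se | intrinsic_only

    # weather model (hourly air temperature, °C)
    t_annual_mean: float = 9.5
    t_seasonal_amplitude: float = 8.5
    t_diurnal_amplitude: float = 4.5
    t_year_offset_sd: float = 1.0
    t_synoptic_sd: float = 3.0      # multi-day weather-system anomalies
    t_synoptic_phi: float = 0.75    # day-to-day persistence
    t_ar_phi: float = 0.8
    t_ar_sigma: float = 0.5
    soil_damping: float = 0.97
    soil_offset: float = 1.0
    precip_occurrence: float = 0.45
    precip_gamma_shape: float = 0.8
    precip_gamma_scale: float = 8.0
    radiation_clear_base: float = 6.0
    radiation_clear_amplitude: float = 22.0

    # tracker noise (AR(p) on rates)
    tracker_ar: tuple = (0.6,)
    tracker_sigma: float = 0.2
    tracker_cadence_min: int = 60
    tracker_span_days: int = 35
    tracker_start_doy: int = 75

    # sparse trait observation model
    trait_scale: float = 30.0       # trait units per compensated unit
    trait_noise_sigma: float = 6.0
    trait_n_dates: int = 11

    # phenology: compensated-time thresholds per stage (per-day units)
    season_start: str = "03-01"     # surrogate for regrowth/sowing stage
    stage_thresholds: dict = field(default_factory=lambda: {
        "jointing": 14.0, "heading": 16.0, "senescence": 20.0})
    threshold_rel_sd: float = 0.10  # genotype earliness variation
    jitter_days: float = 1.0        # uniform ±1 day observation error

    def __post_init__(self) -> None:
        if self.crop == "soybean" and self.n_cultivars == 12:
            # soybean scenario default dimensions
            self.n_cultivars, self.n_years, self.n_reps = 3, 4, 3
        if not self.species_params:
            base = {"wheat": 0.5, "soybean": 5.0}[self.crop]
            if self.response_kind == "asymptotic":
                self.species_params = {"T_min": base, "r_max": 1.0, "s": -2.2}
            elif self.response_kind == "wang_engel":
                self.species_params = {"T_min": base, "T_opt": base + 21.0,
                                       "T_max": base + 32.0, "r_max": 1.0}
            elif self.response_kind in ("linear", "bilinear"):
                self.species_params = {"T_min": max(base, 1.0), "a": 0.05,
                                       "r_min": 0.02}
            else:
                raise ConfigurationError(self.response_kind)
        if not self.cultivar_sd:
            self.cultivar_sd = {
                "r_max": 0.12,
                "T_min": 1.2, "s": 0.35,          # asymptotic per se spread
                "T_opt": 1.5, "T_max": 1.5,       # wang_engel per se spread
                "a": 0.008, "r_min": 0.01,
            }
        if any(v < 0 for v in self.cultivar_sd.values()):
            raise ConfigurationError("cultivar SDs must be >= 0")
        if any(v <= 0 for v in self.stage_thresholds.values()):
            raise ConfigurationError("stage thresholds must be > 0")
        if self.mode not in ("per_se", "intrinsic_only"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    @property
    def cultivar_ids(self) -> list[str]:
        return [f"cv{i + 1:02d}" for i in range(self.n_cultivars)]


@dataclass
class Scenario:
    """A fully generated dataset plus the generating truth."""

    config: ScenarioConfig
    cultivars: dict                 # cultivar_id -> DoseResponseModel
    thresholds: pd.DataFrame        # cultivar x stage compensated thresholds
    air_by_year: dict               # year -> TemperatureSeries
    soil_by_year: dict
    daily_by_year: dict             # year -> DailyWeather DataFrame
    phenology: pd.DataFrame         # cultivar, year, rep, stage, date columns
    periods: pd.DataFrame           # stage_pair period table (t1, t2)

    def temps(self, medium: str = "air") -> dict:
        return self.air_by_year if medium == "air" else self.soil_by_year


# ---------------------------------------------------------------------------

def gen_weather(config: ScenarioConfig, year: int):
    """One year of hourly air/soil temperature plus daily weather."""
    rng = _stream(config.seed, "weather", year)
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31 23:00", freq="h")
    n = len(idx)
    doy = idx.dayofyear.to_numpy(float)
    hod = idx.hour.to_numpy(float)
    seasonal = config.t_seasonal_amplitude * np.sin(
        2 * np.pi * (doy - 110.0) / 365.0)
    diurnal = config.t_diurnal_amplitude * np.sin(
        2 * np.pi * (hod - 9.0) / 24.0)
    year_offset = rng.normal(0.0, config.t_year_offset_sd)

    def ar1(length, phi, sd):
        if sd <= 0:
            return np.zeros(length)
        innov = rng.normal(0.0, sd * np.sqrt(1 - phi**2), length)
        out = np.empty(length)
        out[0] = innov[0] / np.sqrt(1 - phi**2)
        for t in range(1, length):
            out[t] = phi * out[t - 1] + innov[t]
        return out

    # synoptic (weather-system) anomalies persist over days; interpolate to hours
    n_days_syn = int(np.ceil(n / 24)) + 1
    syn_daily = ar1(n_days_syn, config.t_synoptic_phi, config.t_synoptic_sd)
    syn = np.interp(np.arange(n) / 24.0, np.arange(n_days_syn), syn_daily)
    noise = ar1(n, config.t_ar_phi, config.t_ar_sigma)
    air_vals = (config.t_annual_mean + year_offset + seasonal + diurnal
                + syn + noise)
    air = TemperatureSeries(idx, air_vals, medium="air", level="reference")

    lam = config.soil_damping
    soil_vals = np.empty(n)
    soil_vals[0] = air_vals[:24].mean() + config.soil_offset
    for t in range(1, n):
        soil_vals[t] = lam * soil_vals[t - 1] + (1 - lam) * (
            air_vals[t] + config.soil_offset)
    soil = TemperatureSeries(idx, soil_vals, medium="soil", level="plot")

    days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    by_day = pd.Series(air_vals, index=idx).resample("D")
    wet = rng.random(len(days)) < config.precip_occurrence
    amounts = rng.gamma(config.precip_gamma_shape,
                        config.precip_gamma_scale, len(days))
    precip = np.where(wet, amounts, 0.0)
    doy_d = days.dayofyear.to_numpy(float)
    clear = config.radiation_clear_base + config.radiation_clear_amplitude * \
        np.maximum(np.sin(2 * np.pi * (doy_d - 110.0) / 365.0), 0.05)
    cloud = np.where(wet, 0.35, 1.0) * (1.0 - 0.15 * rng.random(len(days)))
    daily = pd.DataFrame({
        "date": days,
        "t_mean": by_day.mean().to_numpy(),
        "t_min": by_day.min().to_numpy(),
        "t_max": by_day.max().to_numpy(),
        "precip_mm": precip,
        "radiation": clear * cloud,
    })
    return air, soil, daily


def gen_cultivars(config: ScenarioConfig) -> dict:
    """Draw cultivar response models around the species means.

    ``intrinsic_only`` varies only r_max (a pure scaling of a shared shape);
    ``per_se`` also varies the shape parameters (cardinal temperatures /
    steepness / slope).  Draws violating model invariants are redrawn
    (bounded retries).
    """
    rng = _stream(config.seed, "cultivars")
    shape_params = {
        "asymptotic": ("T_min", "s"),
        "wang_engel": ("T_min", "T_opt", "T_max"),
        "linear": ("T_min", "a"),
        "bilinear": ("T_min", "a", "r_min"),
    }[config.response_kind]
    out = {}
    for cid in config.cultivar_ids:
        for attempt in range(50):
            params = dict(config.species_params)
            if "r_max" in params:
                params["r_max"] = params["r_max"] * float(
                    np.exp(rng.normal(0.0, config.cultivar_sd.get("r_max", 0.0))))
            if config.mode == "per_se":
                for p in shape_params:
                    params[p] = params[p] + rng.normal(
                        0.0, config.cultivar_sd.get(p, 0.0))
            try:
                out[cid] = DoseResponseModel(config.response_kind,
                                             level="cultivar", cultivar_id=cid,
                                             **params)
                break
            except ConfigurationError:
                continue
        else:
            raise ConfigurationError(
                f"could not draw valid parameters for {cid} in 50 attempts")
    return out


def gen_tracker_series(cultivars: dict, temps: TemperatureSeries,
                       config: ScenarioConfig, *, n_series: int = 2,
                       n_obs: int | None = None) -> pd.DataFrame:
    """Dense rate observations: response(T) + AR(p) noise per leaf series.

    Returns long-format rows (cultivar, series_id, timestamp, temp, rate).
    Cadence and span follow the config; ``n_obs`` caps the points per
    series.
    """
    rows = []
    start = temps.timestamps[0] + pd.Timedelta(days=config.tracker_start_doy)
    step = pd.Timedelta(minutes=config.tracker_cadence_min)
    phi = np.asarray(config.tracker_ar, dtype=float)
    p = len(phi)
    for cid, model in cultivars.items():
        rng = _stream(config.seed, "tracker", zlib.crc32(cid.encode()))
        for k in range(n_series):
            ts = pd.date_range(start, start + pd.Timedelta(days=config.tracker_span_days),
                               freq=step)
            if n_obs is not None:
                ts = ts[:n_obs]
            T = np.interp(ts.asi8, temps.timestamps.asi8, temps.values)
            n = len(ts)
            e = np.zeros(n)
            innov = rng.normal(0.0, config.tracker_sigma, n)
            for t in range(n):
                e[t] = innov[t] + sum(phi[i] * e[t - 1 - i]
                                      for i in range(min(p, t)))
            rate = model(T) + e
            rows.append(pd.DataFrame({
                "cultivar": cid, "series_id": f"{cid}-leaf{k}",
                "timestamp": ts, "temp": T, "rate": rate}))
    return pd.concat(rows, ignore_index=True)


def gen_trait_series(cultivars: dict, temps: TemperatureSeries,
                     config: ScenarioConfig, year: int, *,
                     window=("04-10", "06-10"), trait: str = "height",
                     ) -> list[GrowthSeries]:
    """Sparse trait series: noisy observations of the scaled compensation.

    The latent trajectory is ``trait_scale ×`` the compensated time of the
    cultivar's model from the window start; observation dates are drawn
    within the window; canopy cover is capped at 100%.
    """
    t0 = pd.Timestamp(f"{year}-{window[0]}")
    t1 = pd.Timestamp(f"{year}-{window[1]}")
    out = []
    for cid, model in cultivars.items():
        comp = compensate_time(model, temps, t0)
        rng = _stream(config.seed, "trait", year, zlib.crc32(cid.encode()))
        for rep in range(config.n_reps):
            offs = np.sort(rng.choice(
                np.arange(1, int((t1 - t0) / pd.Timedelta(days=1))),
                size=config.trait_n_dates, replace=False))
            dates = pd.DatetimeIndex([t0 + pd.Timedelta(days=int(d), hours=12)
                                      for d in offs])
            latent = np.array([comp.at(d) for d in dates]) * config.trait_scale
            obs = latent + rng.normal(0.0, config.trait_noise_sigma, len(dates))
            if trait == "canopy_cover":
                obs = np.minimum(obs, 100.0)
            out.append(GrowthSeries(cid, year, f"rep{rep + 1}", trait,
                                    dates, obs,
                                    series_id=f"{cid}-{year}-rep{rep + 1}"))
    return out


def gen_phenology(cultivars: dict, temps_by_year: dict,
                  thresholds: pd.DataFrame, config: ScenarioConfig
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage dates from compensated-time threshold crossings.

    Chained stages per cultivar × year × replication: the vegetative period
    starts at the configured season start; each stage date is the inversion
    of the cultivar's own compensation integral at its genotype-fixed
    threshold.  Observation jitter (uniform ±``jitter_days``) applies to
    recorded dates only, never to the latent chain.  Returns the long stage
    table and the period table (t1, t2 per stage pair).
    """
    stage_names = list(config.stage_thresholds)
    stage_rows, period_rows = [], []
    for year, temps in sorted(temps_by_year.items()):
        t_start = pd.Timestamp(f"{year}-{config.season_start}")
        for cid, model in cultivars.items():
            rng = _stream(config.seed, "phenology", year,
                          zlib.crc32(cid.encode()))
            for rep in range(config.n_reps):
                latent = {"season_start": t_start}
                t_prev = t_start
                for stage in stage_names:
                    thr = float(thresholds.loc[cid, stage])
                    try:
                        t_stage = invert_compensation(model, temps, t_prev, thr)
                    except RangeError as exc:
                        raise RangeError(
                            f"threshold {thr:.3g} for {cid} {stage} "
                            f"unreachable in {year}") from exc
                    latent[stage] = t_stage
                    t_prev = t_stage
                jit = {s: pd.Timedelta(
                    days=float(rng.uniform(-config.jitter_days,
                                           config.jitter_days)))
                       for s in stage_names} if config.jitter_days > 0 else \
                      {s: pd.Timedelta(0) for s in stage_names}
                obs = {"season_start": t_start}
                obs.update({s: latent[s] + jit[s] for s in stage_names})
                for s in stage_names:
                    stage_rows.append({"cultivar": cid, "year": year,
                                       "rep": f"rep{rep + 1}", "stage": s,
                                       "date": obs[s]})
                chain = ["season_start"] + stage_names
                labels = dict(zip(
                    zip(chain[:-1], chain[1:]),
                    ["vegetative", "generative", "maturity"]))
                for (s1, s2), label in labels.items():
                    period_rows.append({
                        "cultivar": cid, "year": year, "rep": f"rep{rep + 1}",
                        "stage_pair": label, "t1": obs[s1], "t2": obs[s2]})
    phen = pd.DataFrame(stage_rows)
    periods = pd.DataFrame(period_rows)
    bad = periods["t1"] >= periods["t2"]
    if bad.any():
        # jitter can only invert a period if stages are closer than 2 days
        raise ConfigurationError(
            "observation jitter inverted a period; reduce jitter_days")
    return phen, periods


def _gen_thresholds(config: ScenarioConfig) -> pd.DataFrame:
    rng = _stream(config.seed, "thresholds")
    rows = {}
    for cid in config.cultivar_ids:
        rows[cid] = {s: base * float(np.exp(rng.normal(0.0, config.threshold_rel_sd)))
                     for s, base in config.stage_thresholds.items()}
    return pd.DataFrame(rows).T


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate the full scenario: weather, cultivars, phenology."""
    cultivars = gen_cultivars(config)
    thresholds = _gen_thresholds(config)
    air, soil, daily = {}, {}, {}
    for year in config.years:
        a, s, d = gen_weather(config, year)
        air[year], soil[year], daily[year] = a, s, d
    phen, periods = gen_phenology(cultivars, air, thresholds, config)
    return Scenario(config=config, cultivars=cultivars, thresholds=thresholds,
                    air_by_year=air, soil_by_year=soil, daily_by_year=daily,
                    phenology=phen, periods=periods)
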