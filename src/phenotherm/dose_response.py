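"""Temperature dose-response models and temperature compensation of time.

The developmental clock of a crop can be re-expressed by replacing calendar
time with the accumulated value of a temperature response function r(T):

    y(t) = integral_{t0}^{t} r(T(t')) dt'

("linearized" or temperature-compensated time).  The classic special case is
thermal time / growing degree days, where r(T) = max(T - T_min, 0) with a
literature base temperature.  This module implements four parametric response
families — thermal time / linear, bilinear, asymptotic (monotone saturating)
and Wang–Engel (beta-shaped with cardinal temperatures T_min < T_opt < T_max)
— together with the step-sum compensation integral on an hourly temperature
grid and its inverse (which calendar instant reaches a given compensated
amount).

Units: response rates are per hour internally; all public cumulative
compensated values are reported per day (hourly sum / 24), so thermal-time
compensation reads directly in °C·d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, RangeError

__all__ = [
    "TemperatureSeries",
    "DoseResponseModel",
    "CompensatedSeries",
    "SPECIES_BASE_TEMP",
    "eval_response",
    "compensate_time",
    "invert_compensation",
]

#: literature base temperatures (°C) for the thermal-time special case
SPECIES_BASE_TEMP: Mapping[str, float] = {"wheat": 0.0, "soybean": 5.0}

MODEL_KINDS = ("thermal_time", "linear", "bilinear", "asymptotic", "wang_engel")


@dataclass
class TemperatureSeries:
    """An ordered temperature course (hourly or finer).

    Parameters
    ----------
    timestamps : pandas.DatetimeIndex
        Strictly increasing, timezone-naive instants.
    values : ndarray
        Temperatures in °C, no missing values.
    medium : {"air", "soil"}
    level : {"plot", "reference"}
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    medium: str = "air"
    level: str = "reference"

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise DataError("timestamps and values differ in length")
        if len(self.values) < 2:
            raise DataError("temperature series needs at least 2 points")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise DataError("timestamps must be strictly increasing")
        if self.timestamps.tz is not None:
            raise DataError("timestamps must be timezone-naive local time")
        if not np.all(np.isfinite(self.values)):
            raise DataError("temperature values contain NaN/inf")
        if self.medium not in ("air", "soil"):
            raise DataError(f"unknown medium {self.medium!r}")
        if self.level not in ("plot", "reference"):
            raise DataError(f"unknown level {self.level!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.timestamps[0], self.timestamps[-1]

    def check_gaps(self, max_gap_hours: float = 3.0) -> None:
        """Raise :class:`DataError` if any step exceeds ``max_gap_hours``."""
        steps = np.diff(self.timestamps.asi8) / 3.6e12
        if steps.size and steps.max() > max_gap_hours:
            raise DataError(
                f"temperature gap of {steps.max():.2f} h exceeds "
                f"tolerance of {max_gap_hours} h"
            )

    def slice(self, t0, t1) -> "TemperatureSeries":
        mask = (self.timestamps >= pd.Timestamp(t0)) & (self.timestamps <= pd.Timestamp(t1))
        return TemperatureSeries(self.timestamps[mask], self.values[mask],
                                 self.medium, self.level)


@dataclass
class DoseResponseModel:
    """A parametric temperature response r(T) >= 0.

    kind:
      - ``thermal_time``: r = max(T - T_min, 0), slope fixed to a = 1,
        T_min from species defaults (species-level literature model).
      - ``linear``: r = max(a (T - T_min), 0) with both parameters free.
      - ``bilinear``: r = max(T/T_min * r_min, r_min + a (T - T_min), 0);
        a gentler rise up to T_min, slope a above.  Requires T_min > 0.
      - ``asymptotic``: r = max(r_max (1 - exp(-exp(s) (T - T_min))), 0);
        s is the log rate constant ("lrc") controlling steepness.
      - ``wang_engel``: beta-shaped with cardinal temperatures
        T_min < T_opt < T_max, maximum r_max at T_opt, zero outside.
    """

    kind: str
    T_min: float = 0.0
    a: float = 1.0
    r_min: float = 0.0
    r_max: float = 1.0
    s: float = 0.0
    T_opt: float = 25.0
    T_max: float = 35.0
    level: str = "species"
    cultivar_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ConfigurationError(f"unknown model kind {self.kind!r}")
        if self.level not in ("species", "cultivar"):
            raise ConfigurationError(f"unknown level {self.level!r}")
        if self.kind == "thermal_time":
            self.a = 1.0
        if self.kind == "bilinear":
            if self.T_min <= 0:
                raise ConfigurationError(
                    "bilinear model requires T_min > 0 (T_min divides the "
                    "sub-threshold segment)")
            if self.r_min < 0:
                raise ConfigurationError("bilinear r_min must be >= 0")
            if self.a < self.r_min / self.T_min:
                warnings.warn(
                    "bilinear slope a < r_min/T_min produces a kink artifact: "
                    "the sub-threshold segment overtakes the main segment",
                    stacklevel=2)
        if self.kind in ("asymptotic", "wang_engel") and self.r_max <= 0:
            raise ConfigurationError("r_max must be > 0")
        if self.kind == "wang_engel":
            if not (self.T_min < self.T_opt < self.T_max):
                raise ConfigurationError(
                    f"wang_engel needs T_min < T_opt < T_max, got "
                    f"({self.T_min}, {self.T_opt}, {self.T_max})")
            alpha = self.alpha
            if not np.isfinite(alpha) or alpha <= 0:
                raise ConfigurationError("wang_engel alpha is not finite/positive")

    @property
    def alpha(self) -> float:
        """Wang–Engel shape exponent: ln 2 / ln((T_max−T_min)/(T_opt−T_min))."""
        return float(np.log(2.0) /
                     np.log((self.T_max - self.T_min) / (self.T_opt - self.T_min)))

    @classmethod
    def thermal_time(cls, crop: str = "wheat", **kw) -> "DoseResponseModel":
        """Species-level thermal time with the literature base temperature."""
        if crop not in SPECIES_BASE_TEMP:
            raise ConfigurationError(f"no base-temperature default for crop {crop!r}")
        return cls(kind="thermal_time", T_min=SPECIES_BASE_TEMP[crop], a=1.0, **kw)

    # -- evaluation --------------------------------------------------------

    def __call__(self, T) -> np.ndarray:
        return eval_response(self, T)

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Names of the parameters estimated from data for this kind."""
        return {
            "thermal_time": (),
            "linear": ("T_min", "a"),
            "bilinear": ("T_min", "a", "r_min"),
            "asymptotic": ("T_min", "r_max", "s"),
            "wang_engel": ("T_min", "T_opt", "T_max", "r_max"),
        }[self.kind]

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "level": self.level}
        if self.cultivar_id is not None:
            d["cultivar_id"] = self.cultivar_id
        names = self.free_parameters or ("T_min", "a")
        for p in names:
            d[p] = float(getattr(self, p))
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DoseResponseModel":
        return cls(**{k: v for k, v in d.items()})


def eval_response(model: DoseResponseModel | Callable, T) -> np.ndarray:
    """Evaluate the response rate at temperature(s) ``T`` (°C), clipped at 0.

    ``model`` may also be any plain callable rate(T) (e.g. a fitted
    semiparametric response); it is then called directly and clipped.
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise DataError("temperature input contains NaN/inf")
    if not isinstance(model, DoseResponseModel):
        return np.maximum(np.asarray(model(T), dtype=float), 0.0)

    k = model.kind
    if k in ("thermal_time", "linear"):
        r = model.a * (T - model.T_min)
    elif k == "bilinear":
        r = np.maximum(T / model.T_min * model.r_min,
                       model.r_min + (T - model.T_min) * model.a)
    elif k == "asymptotic":
        r = model.r_max * (1.0 - np.exp(-np.exp(model.s) * (T - model.T_min)))
    elif k == "wang_engel":
        al = model.alpha
        with np.errstate(invalid="ignore"):
            dT = np.maximum(T - model.T_min, 0.0)
            dO = model.T_opt - model.T_min
            r = model.r_max * (2.0 * dT**al * dO**al - dT**(2 * al)) / dO**(2 * al)
        r = np.where((T <= model.T_min) | (T >= model.T_max), 0.0, r)
    else:  # pragma: no cover
        raise ConfigurationError(k)
    return np.maximum(r, 0.0)


@dataclass
class CompensatedSeries:
    """Cumulative compensated time on the covariate grid (per-day units)."""

    timestamps: pd.DatetimeIndex
    cumulative: np.ndarray  # non-decreasing, cumulative[0] == 0
    t0: pd.Timestamp = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.t0 is None:
            self.t0 = self.timestamps[0]
        if abs(self.cumulative[0]) > 1e-12:
            raise DataError("cumulative must start at 0")
        if np.any(np.diff(self.cumulative) < -1e-12):
            raise DataError("cumulative must be non-decreasing")

    @property
    def total(self) -> float:
        return float(self.cumulative[-1])

    def at(self, t) -> float:
        """Cumulative value at instant ``t`` (linear within a step)."""
        t = pd.Timestamp(t)
        x = self.timestamps.asi8
        return float(np.interp(t.value, x, self.cumulative))


def _step_hours(index: pd.DatetimeIndex) -> np.ndarray:
    """Left-step durations in hours; the final point closes with zero width."""
    dt = np.diff(index.asi8) / 3.6e12
    return np.append(dt, 0.0)


def compensate_time(model, temps: TemperatureSeries, t0=None, *,
                    max_gap_hours: float = 3.0) -> CompensatedSeries:
    """Integrate the response over the temperature course from ``t0``.

    The integral is a left-step (rectangle) sum on the covariate grid: the
    rate at each recorded temperature applies until the next record.  Values
    are reported per day (hourly step sum divided by 24), so thermal time
    accumulates in °C·d.  ``t0`` defaults to the start of the series and may
    fall between grid points (partial first step, linear in time).
    """
    temps.check_gaps(max_gap_hours)
    t0 = temps.timestamps[0] if t0 is None else pd.Timestamp(t0)
    lo, hi = temps.span
    if not (lo <= t0 <= hi):
        raise RangeError(f"t0 {t0} outside temperature span [{lo}, {hi}]")

    rates = eval_response(model, temps.values)
    widths = _step_hours(temps.timestamps)
    increments = rates * widths / 24.0
    cum = np.concatenate([[0.0], np.cumsum(increments[:-1])])
    # shift origin to t0 (subtract cumulative at t0, clamp before t0 to 0);
    # linear interpolation is exact: cumulative is piecewise linear in time
    full = CompensatedSeries(temps.timestamps, cum, temps.timestamps[0])
    offset = full.at(t0)
    shifted = np.maximum(full.cumulative - offset, 0.0)
    return CompensatedSeries(temps.timestamps, shifted, t0)


def invert_compensation(model, temps: TemperatureSeries, t1, target: float, *,
                        max_gap_hours: float = 3.0) -> pd.Timestamp:
    """Earliest instant t2 with compensated time from ``t1`` >= ``target``.

    ``target`` is in the per-day units of :func:`compensate_time`.  Linear
    interpolation is used within the step where the threshold is crossed.
    """
    if target < 0:
        raise RangeError("target must be >= 0")
    t1 = pd.Timestamp(t1)
    if target == 0:
        return t1
    comp = compensate_time(model, temps, t1, max_gap_hours=max_gap_hours)
    cum = comp.cumulative
    if cum[-1] < target:
        raise RangeError(
            f"target {target:.4g} unreachable: series accumulates only "
            f"{cum[-1]:.4g} after {t1}")
    idx = int(np.searchsorted(cum, target, side="left"))
    x = temps.timestamps.asi8.astype(float)
    if cum[idx] == target:
        return pd.Timestamp(int(x[idx]))
    # crossing inside step (idx-1, idx)
    c0, c1 = cum[idx - 1], cum[idx]
    frac = (target - c0) / (c1 - c0)
    t_ns = x[idx - 1] + frac * (x[idx] - x[idx - 1])
    t2 = pd.Timestamp(int(t_ns))
    return max(t2, t1)
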