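"""Environmental stress indices and residual attribution.

Daily weather (mean/min/max temperature, precipitation, global radiation)
is condensed into stress indices per phenological period:

* **SPI** — standardized precipitation index: 30-day rolling precipitation
  sums mapped through a fitted zero-inflated gamma distribution onto the
  standard normal quantile scale.
* **SPEI** — the same transform on the climatic water balance
  D = precipitation − potential evapotranspiration, with PET from the
  Thornthwaite temperature/day-length formula and a three-parameter
  log-logistic distribution fitted by probability-weighted moments.
* **cold stress** — the accumulated magnitude of daily minimum temperatures
  below 0 °C (°C·d, positive convention).
* **moisture/drought extremes** — sums of SPI/SPEI values beyond ±1 and
  ±1.75 within a period.

Standard orientation throughout: positive SPI/SPEI = wet.  ``sign_flip``
inverts the reported series for workflows that read positive values as dry.

Per period the minimum, maximum and cumulative value of each daily index is
tabulated; a lasso regression (λ grid 1e-8..5, α=1, repeated 5-fold CV with
10 repeats) then attributes phenology-prediction residuals to the indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.stats import fisk, gamma as gamma_dist, norm
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import RepeatedKFold

from .errors import DataError, MetricError

__all__ = [
    "WEATHER_COLUMNS", "LassoAttribution",
    "validate_weather", "thornthwaite_pet", "spi", "spei",
    "cold_stress_index", "extreme_indices", "build_index_table",
    "lasso_residuals",
]

WEATHER_COLUMNS = ("date", "t_mean", "t_min", "t_max", "precip_mm", "radiation")


def validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Schema/invariant check; returns a date-indexed copy."""
    missing = [c for c in WEATHER_COLUMNS if c not in weather.columns]
    if missing:
        raise DataError(f"weather table lacks columns {missing}")
    w = weather.copy()
    w["date"] = pd.DatetimeIndex(w["date"])
    w = w.set_index("date").sort_index()
    if w.index.has_duplicates:
        raise DataError("duplicate weather dates")
    if (w["precip_mm"] < 0).any():
        raise DataError("negative precipitation")
    bad = (w["t_min"] > w["t_mean"]) | (w["t_mean"] > w["t_max"])
    if bad.any():
        raise DataError(f"t_min <= t_mean <= t_max violated on {bad.sum()} days")
    return w


# ---------------------------------------------------------------------------
# Thornthwaite potential evapotranspiration

def _day_length_hours(doy: np.ndarray, latitude_deg: float) -> np.ndarray:
    phi = np.deg2rad(latitude_deg)
    decl = 0.409 * np.sin(2 * np.pi / 365.0 * doy - 1.39)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_omega)


def thornthwaite_pet(t_mean: pd.Series, latitude_deg: float) -> pd.Series:
    """Daily Thornthwaite PET (mm/day) from daily mean temperatures.

    Monthly PET = 16 K (10 T / I)^a with the annual heat index
    I = sum over months of (T/5)^1.514 (months with T > 0) and the day-length
    correction K = (mean day length / 12) * (days in month / 30); monthly
    values are disaggregated to daily by division.  Months with T <= 0 get
    PET 0 (Thornthwaite convention).  The heat index is computed per
    calendar year; incomplete years fall back to the record's monthly
    climatology, which is also why at least 12 months of data are required.
    """
    t_mean = t_mean.sort_index()
    idx = pd.DatetimeIndex(t_mean.index)
    if idx.to_period("M").nunique() < 12:
        raise DataError("Thornthwaite heat index needs >= 12 months of data")
    monthly = t_mean.groupby([idx.year, idx.month]).mean()
    monthly.index.names = ["year", "month"]
    clim = monthly.groupby("month").mean()

    def heat_index(vals: pd.Series) -> float:
        pos = vals[vals > 0]
        return float(((pos / 5.0) ** 1.514).sum())

    pet = pd.Series(0.0, index=idx)
    for year in np.unique(idx.year):
        ym = monthly.loc[year]
        full = ym.reindex(range(1, 13))
        full = full.fillna(clim)
        I = heat_index(full)
        if I <= 0:
            continue  # all-frozen year: PET stays 0
        a = (6.75e-7 * I**3 - 7.71e-5 * I**2 + 1.792e-2 * I + 0.49239)
        for month in ym.index:
            Tm = ym[month]
            sel = (idx.year == year) & (idx.month == month)
            if Tm <= 0:
                continue
            days = idx[sel]
            N = len(days)
            L = _day_length_hours(days.dayofyear.to_numpy(float), latitude_deg).mean()
            K = (L / 12.0) * (N / 30.0)
            pet_month = 16.0 * K * (10.0 * Tm / I) ** a
            pet[sel] = pet_month / N
    return pd.Series(pet.to_numpy(), index=idx, name="pet")


# ---------------------------------------------------------------------------
# standardized indices

def _rolling_sums(series: pd.Series, window: int) -> pd.Series:
    s = series.sort_index()
    return s.rolling(window=window, min_periods=window).sum().dropna()


def spi(precip: pd.Series, window: int = 30, *,
        sign_flip: bool = False, return_fit: bool = False):
    """Standardized precipitation index with a ``window``-day accumulation.

    The distribution of rolling sums is fitted over the whole record as the
    zero-inflated gamma q + (1−q)·Gamma(shape, scale) (gamma by ML on the
    positive sums); probabilities map through the standard normal quantile.
    With ``return_fit=True`` also returns the fitted mixture parameters
    ``{"q", "shape", "scale"}``.
    """
    sums = _rolling_sums(precip, window)
    if len(sums) < 2 * 365 - window:
        raise DataError("SPI distribution fitting needs >= 2 years of data")
    x = sums.to_numpy(float)
    pos = x[x > 0]
    if pos.size == 0:
        raise MetricError("all-zero precipitation: SPI undefined")
    q = 1.0 - pos.size / x.size
    shape, _, scale = gamma_dist.fit(pos, floc=0.0)
    prob = np.where(x > 0, q + (1 - q) * gamma_dist.cdf(x, shape, scale=scale),
                    q if q > 0 else 0.5 / x.size)
    prob = np.clip(prob, 1e-8, 1 - 1e-8)
    z = norm.ppf(prob)
    out = pd.Series(-z if sign_flip else z, index=sums.index, name="spi")
    if return_fit:
        return out, {"q": float(q), "shape": float(shape),
                     "scale": float(scale)}
    return out


def _loglogistic_pwm(x: np.ndarray) -> tuple[float, float, float, bool]:
    """Three-parameter log-logistic by probability-weighted moments.

    Returns (shape, scale, location, reflected).  The log-logistic is
    right-skewed; for left-skewed samples the reflected series −x is fitted
    instead (``reflected=True``) and the caller maps probabilities through
    the complement.
    """
    def pwm_fit(xs):
        n = xs.size
        i = np.arange(1, n + 1)
        # alpha-type PWMs w_s = E[X (1-F)^s], unbiased estimators
        w0 = xs.mean()
        w1 = float(np.sum((n - i) / (n - 1) * xs) / n)
        w2 = float(np.sum((n - i) * (n - i - 1) /
                          ((n - 1) * (n - 2)) * xs) / n)
        beta = (2 * w1 - w0) / (6 * w1 - w0 - 6 * w2)
        return w0, w1, beta

    xs = np.sort(x)
    w0, w1, beta = pwm_fit(xs)
    reflected = False
    if np.isfinite(beta) and beta < 0:
        xs = np.sort(-x)
        w0, w1, beta = pwm_fit(xs)
        reflected = True
    if not np.isfinite(beta) or beta <= 1.0:
        raise MetricError(f"log-logistic PWM shape {beta!r} invalid (<= 1)")
    g1g2 = gamma_fn(1 + 1 / beta) * gamma_fn(1 - 1 / beta)
    alpha = (w0 - 2 * w1) * beta / g1g2
    gam = w0 - alpha * g1g2
    return float(beta), float(alpha), float(gam), reflected


def spei(precip: pd.Series, pet: pd.Series, window: int = 30, *,
         sign_flip: bool = False) -> pd.Series:
    """Standardized precipitation-evapotranspiration index.

    Operates on the water balance D = precip − PET; rolling ``window``-day
    sums are fitted by a three-parameter log-logistic distribution
    (probability-weighted moments) and mapped through the normal quantile.
    """
    d = (precip - pet).dropna()
    sums = _rolling_sums(d, window)
    if len(sums) < 2 * 365 - window:
        raise DataError("SPEI distribution fitting needs >= 2 years of data")
    x = sums.to_numpy(float)
    beta, alpha, gam, reflected = _loglogistic_pwm(x)
    if reflected:
        prob = fisk.sf(-x, beta, loc=gam, scale=alpha)
    else:
        prob = fisk.cdf(x, beta, loc=gam, scale=alpha)
    prob = np.clip(prob, 1e-8, 1 - 1e-8)
    z = norm.ppf(prob)
    return pd.Series(-z if sign_flip else z, index=sums.index, name="spei")


# ---------------------------------------------------------------------------
# period summaries

def _period_mask(index: pd.DatetimeIndex, t1, t2) -> np.ndarray:
    """Half-open day window [t1, t2) so adjacent periods tile additively."""
    return (index >= pd.Timestamp(t1)) & (index < pd.Timestamp(t2))


def cold_stress_index(t_min: pd.Series, t1, t2) -> float:
    """Accumulated frost magnitude sum(max(0, −t_min)) over [t1, t2), °C·d."""
    sel = t_min[_period_mask(pd.DatetimeIndex(t_min.index), t1, t2)]
    return float(np.maximum(0.0, -sel.to_numpy(float)).sum())


def extreme_indices(index_series: pd.Series, t1, t2,
                    thresholds=(1.0, 1.75)) -> dict:
    """Sums of index values beyond ±thresholds within [t1, t2)."""
    sel = index_series[_period_mask(pd.DatetimeIndex(index_series.index),
                                    t1, t2)].to_numpy(float)
    out = {}
    for thr in thresholds:
        key = f"{thr:g}".replace(".", "p")
        out[f"above_{key}"] = float(sel[sel > thr].sum())
        out[f"below_{key}"] = float(sel[sel < -thr].sum())
    return out


def build_index_table(weather: pd.DataFrame, periods_by_year: dict, *,
                      latitude_deg: float = 47.45, window: int = 30,
                      sign_flip: bool = False) -> pd.DataFrame:
    """Min/max/cumulative environmental indices per year × period.

    ``periods_by_year`` maps year -> {period name -> (t1, t2)}.  Daily base
    indices: t_mean, t_min, t_max, precipitation, radiation, SPI, SPEI;
    plus the cold-stress sum and the four SPI and SPEI extreme sums.
    """
    w = validate_weather(weather.reset_index() if "date" not in weather.columns
                         else weather)
    pet = thornthwaite_pet(w["t_mean"], latitude_deg)
    daily = {
        "t_mean": w["t_mean"], "t_min": w["t_min"], "t_max": w["t_max"],
        "precip": w["precip_mm"], "radiation": w["radiation"],
        "spi": spi(w["precip_mm"], window, sign_flip=sign_flip),
        "spei": spei(w["precip_mm"], pet, window, sign_flip=sign_flip),
    }
    rows = []
    for year, periods in sorted(periods_by_year.items()):
        for period, (t1, t2) in periods.items():
            if pd.Timestamp(t1) < w.index[0] or pd.Timestamp(t2) > w.index[-1] + pd.Timedelta(days=1):
                raise DataError(f"weather does not cover {period} {year}")
            rec = {"year": year, "period": period}
            for name, s in daily.items():
                sel = s[_period_mask(pd.DatetimeIndex(s.index), t1, t2)]
                if sel.empty:
                    raise DataError(f"no index days inside {period} {year}")
                rec[f"{name}_min"] = float(sel.min())
                rec[f"{name}_max"] = float(sel.max())
                rec[f"{name}_cum"] = float(sel.sum())
            rec["cold_stress"] = cold_stress_index(w["t_min"], t1, t2)
            for nm in ("spi", "spei"):
                for k, v in extreme_indices(daily[nm], t1, t2).items():
                    rec[f"{nm}_{k}"] = v
            rows.append(rec)
    return pd.DataFrame(rows).set_index(["year", "period"])


# ---------------------------------------------------------------------------
# lasso attribution

@dataclass
class LassoAttribution:
    coefficients: pd.Series      # on the centered/scaled feature scale
    intercept: float
    lambda_: float
    cv_curve: pd.Series          # lambda -> mean CV MSE
    feature_means: pd.Series
    feature_scales: pd.Series
    seed: int

    @property
    def selected(self) -> pd.Series:
        return self.coefficients[self.coefficients != 0.0]


def lasso_residuals(residuals, features: pd.DataFrame, seed: int, *,
                    lambdas=None, n_folds: int = 5,
                    n_repeats: int = 10, rule: str = "min"
                    ) -> LassoAttribution:
    """Attribute phenology residuals to environmental indices by lasso.

    Features are centered and scaled internally; λ runs over a log grid
    from 1e-8 to 5 (α = 1, pure lasso) and is chosen by repeated
    ``n_folds``-fold CV (``n_repeats`` repeats) minimizing MSE
    (``rule="min"``, the default).  ``rule="1se"`` picks the largest λ
    whose CV error is within one standard error of the minimum — the
    selection-consistent choice when the sparse support itself is of
    interest (CV-min is prediction-optimal and tends to keep small spurious
    coefficients).  Constant residuals yield the null model (all
    coefficients zero).
    """
    y = np.asarray(residuals, dtype=float)
    X = features.to_numpy(float)
    if len(y) != len(X):
        raise DataError("residuals/features length mismatch")
    if len(y) <= 5:
        raise DataError("need more than 5 observations")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, keep] = (X[:, keep] - mu[keep]) / sd[keep]

    names = list(features.columns)
    if np.std(y) == 0:
        zero = pd.Series(0.0, index=names)
        return LassoAttribution(zero, float(y.mean()), np.inf,
                                pd.Series(dtype=float),
                                pd.Series(mu, index=names),
                                pd.Series(sd, index=names), seed)

    lambdas = (np.logspace(-8, np.log10(5.0), 60) if lambdas is None
               else np.asarray(lambdas, dtype=float))
    order = np.argsort(lambdas)[::-1]          # lasso_path wants descending
    lam_desc = lambdas[order]
    cv = RepeatedKFold(n_splits=n_folds, n_repeats=n_repeats,
                       random_state=seed)
    folds = list(cv.split(Xs))
    fold_mse = np.zeros((len(folds), len(lambdas)))
    for k, (tr, te) in enumerate(folds):
        ybar = y[tr].mean()
        _, coefs, _ = lasso_path(Xs[tr], y[tr] - ybar, alphas=lam_desc,
                                 max_iter=20000, tol=1e-8)
        pred = Xs[te] @ coefs + ybar           # (n_te, n_lambda)
        fold_mse[k] = np.mean((y[te][:, None] - pred) ** 2, axis=0)
    mse_desc = fold_mse.mean(axis=0)
    mse = np.empty_like(mse_desc)
    mse[order] = mse_desc
    best = int(np.argmin(mse))
    if rule == "1se":
        # SE of a single n_folds-CV estimate: spread across the repeats
        rep = fold_mse.reshape(n_repeats, n_folds, -1).mean(axis=1)
        se = rep.std(axis=0, ddof=1) if n_repeats > 1 else \
            fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
        se_min = np.empty_like(mse)
        se_min[order] = se
        ok = np.nonzero(mse <= mse.min() + se_min[best])[0]
        best = int(ok[-1]) if len(ok) else best  # grid ascending: largest λ
    elif rule != "min":
        raise DataError(f"unknown selection rule {rule!r}")
    lam = float(lambdas[best])
    final = Lasso(alpha=lam, max_iter=100000, tol=1e-10)
    final.fit(Xs, y)
    return LassoAttribution(
        coefficients=pd.Series(final.coef_, index=names),
        intercept=float(final.intercept_), lambda_=lam,
        cv_curve=pd.Series(mse, index=lambdas),
        feature_means=pd.Series(mu, index=names),
        feature_scales=pd.Series(sd, index=names), seed=seed)
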