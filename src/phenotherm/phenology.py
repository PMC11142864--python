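"""Phenology-period linearization and G×E variance decomposition.

The duration of a phenological period (sowing→jointing, jointing→heading,
heading→senescence) is re-expressed in temperature-compensated time by
integrating a genotype's response model between the observed stage dates:

    y_ijk = integral_{t1}^{t2} r(theta_i; T_t) dt.

If the response model matches the genotype's true temperature physiology,
y_ijk is a genotype constant across years; a mismatched (e.g. species-level
thermal time) model leaks year-dependent signal into y_ijk that a mixed
model then attributes to genotype-by-year interaction.  After scaling y to a
per-genotype mean of one, the decomposition

    y_ijk = mu + v_j + g_i + (vg)_ij + e_ijk

(fixed year v_j, random genotype g_i, random interaction with year-specific
"diagonal" variances) yields the share of genotypic variance due to G×E,
pct_gxe = sigma2_vg / (sigma2_vg + sigma2_g) * 100, Spearman rank
correlations of year-specific vs overall genotype predictions, and — by
inverting the compensation integral — prediction RMSEs in calendar days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .dose_response import TemperatureSeries, compensate_time, invert_compensation
from .errors import DataError, RangeError
from .fitting import GrowthSeries
from .mixed import RandomBlock, fit_reml

__all__ = [
    "STAGE_PAIRS", "GxEDecomposition",
    "linearize_period", "linearize_dataset", "scale_per_genotype",
    "normalize_durations", "rate_unit", "fit_gxe_model", "gxe_contrast",
    "predict_rmse_days", "residual_days", "estimate_jointing_qmer",
]

#: canonical period names and their aliases
STAGE_PAIRS = {
    "vegetative": ("sowing", "jointing"),
    "generative": ("jointing", "heading"),
    "maturity": ("heading", "senescence"),
}

PERIOD_COLUMNS = ("cultivar", "year", "rep", "stage_pair", "t1", "t2")


@dataclass
class GxEDecomposition:
    mu: float
    year_effects: pd.Series          # fixed v_j (first year as reference 0)
    g: pd.Series                     # genotype BLUPs
    vg: pd.DataFrame                 # interaction BLUPs, genotype x year
    sigma2_g: float
    sigma2_vg_by_year: pd.Series
    sigma2_vg: float                 # aggregated (mean of year variances)
    pct_gxe: float
    spearman_by_year: pd.Series
    sigma2_e: float
    rmse_days: float | None = None
    boundary_flags: dict = field(default_factory=dict)
    reml_fit: object = field(default=None, repr=False)


def _check_period_frame(periods: pd.DataFrame) -> None:
    missing = [c for c in PERIOD_COLUMNS if c not in periods.columns]
    if missing:
        raise DataError(f"period table lacks columns {missing}")


def linearize_period(model, temps: TemperatureSeries, t1, t2) -> float:
    """Compensated duration of one period [t1, t2] under ``model``."""
    t1, t2 = pd.Timestamp(t1), pd.Timestamp(t2)
    if not (t1 < t2):
        raise DataError(f"period start {t1} not before end {t2}")
    lo, hi = temps.span
    if t1 < lo or t2 > hi:
        raise DataError(f"temperature series does not cover [{t1}, {t2}]")
    return compensate_time(model, temps, t1).at(t2)


def linearize_dataset(models, periods: pd.DataFrame,
                      temps_by_year: dict) -> pd.DataFrame:
    """Add the compensated duration column ``y`` to a period table.

    ``models`` is either one response model applied to every genotype
    (species level / thermal time) or a ``{cultivar: model}`` mapping.
    """
    _check_period_frame(periods)
    out = periods.copy()
    y = np.empty(len(out))
    for pos, row in enumerate(out.itertuples(index=False)):
        model = models[row.cultivar] if isinstance(models, dict) else models
        y[pos] = linearize_period(model, temps_by_year[row.year],
                                  row.t1, row.t2)
    out["y"] = y
    return out


def scale_per_genotype(periods: pd.DataFrame, col: str = "y") -> pd.DataFrame:
    """Scale compensated durations to a per-genotype mean of one.

    Note that in a *balanced* design this scaling makes the genotype main
    effect exactly collinear with the scaling constraint (every genotype's
    sample mean is one), so a subsequent variance decomposition cannot
    identify sigma2_g.  :func:`normalize_durations` with the default
    rate-unit method avoids this; the mean-one scaling is kept for
    comparability-only uses and unbalanced data.
    """
    out = periods.copy()
    means = out.groupby("cultivar")[col].transform("mean")
    if np.any(np.abs(means.to_numpy()) < 1e-300):
        raise DataError("a genotype has zero mean compensated duration")
    out["y_scaled"] = out[col] / means
    return out


def rate_unit(model, t_grid=None) -> float:
    """Intrinsic rate unit of a response model.

    The mean response over a fixed reference temperature grid (0..30 °C).
    Dividing a compensated duration by this unit expresses it in
    "equivalent days at the reference climate", a scale comparable across
    cultivar-specific models.
    """
    from .dose_response import eval_response
    t_grid = np.linspace(0.0, 30.0, 61) if t_grid is None else t_grid
    u = float(np.mean(eval_response(model, t_grid)))
    if u <= 0:
        raise DataError("response model has zero mean rate on 0-30 °C")
    return u


def normalize_durations(periods: pd.DataFrame, models,
                        method: str = "rate_unit"
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Express compensated durations on a genotype-comparable scale.

    ``method='rate_unit'`` divides each genotype's y by its model's
    intrinsic rate unit — removing the units artifact of cultivar-specific
    parameter scales while preserving real earliness differences (the
    genotype main effect stays identifiable).  ``method='genotype_mean'``
    is the mean-one scaling.  Returns the table with ``y_scaled`` plus the
    per-genotype divisors (needed to map predictions back to y units).
    """
    genos = sorted(periods["cultivar"].unique())
    if method == "rate_unit":
        div = pd.Series({g: rate_unit(models[g] if isinstance(models, dict)
                                      else models) for g in genos})
        out = periods.copy()
        out["y_scaled"] = out["y"] / div.loc[out["cultivar"]].to_numpy()
    elif method == "genotype_mean":
        out = scale_per_genotype(periods)
        div = out.groupby("cultivar")["y"].mean()
    else:
        raise DataError(f"unknown normalization {method!r}")
    return out, div


def fit_gxe_model(periods: pd.DataFrame, *, response_col: str = "y_scaled",
                  row_range_effects: bool = False,
                  vg_aggregation: str = "mean") -> GxEDecomposition:
    """REML fit of the G×E decomposition on scaled compensated durations.

    Random genotype effects share one variance; genotype-by-year interaction
    effects get a separate variance per year (diagonal structure).  Optional
    iid row/range/row-by-range random effects absorb spatial trends when the
    period table carries ``row``/``range`` columns.  ``vg_aggregation``
    ("mean" or "sum") controls how year-specific interaction variances are
    pooled into the reported sigma2_vg.
    """
    genos = sorted(periods["cultivar"].unique())
    years = sorted(periods["year"].unique())
    if len(genos) < 2 or len(years) < 2:
        raise DataError("G×E decomposition needs >= 2 genotypes and >= 2 years")
    y = periods[response_col].to_numpy(float)
    n = len(y)

    X = np.column_stack(
        [np.ones(n)] + [(periods["year"] == yr).to_numpy(float)
                        for yr in years[1:]])
    beta_names = ["mu"] + [f"v_{yr}" for yr in years[1:]]

    Zg = np.column_stack([(periods["cultivar"] == g).to_numpy(float)
                          for g in genos])
    cells = [(g, yr) for yr in years for g in genos]
    Zvg = np.column_stack([
        ((periods["cultivar"] == g) & (periods["year"] == yr)).to_numpy(float)
        for g, yr in cells])
    vg_groups = np.repeat(np.arange(len(years)), len(genos))
    blocks = [RandomBlock("g", Zg, level_names=genos),
              RandomBlock("vg", Zvg, groups=vg_groups, level_names=cells)]
    if row_range_effects:
        for eff in ("row", "range"):
            if eff not in periods.columns:
                raise DataError(f"row_range_effects requested but no {eff!r} column")
        lv_row = sorted(periods["row"].unique())
        lv_rng = sorted(periods["range"].unique())
        blocks.append(RandomBlock("row", np.column_stack(
            [(periods["row"] == r).to_numpy(float) for r in lv_row])))
        blocks.append(RandomBlock("range", np.column_stack(
            [(periods["range"] == r).to_numpy(float) for r in lv_rng])))
        cells_rr = [(a, b) for a in lv_row for b in lv_rng]
        blocks.append(RandomBlock("row_range", np.column_stack(
            [((periods["row"] == a) & (periods["range"] == b)).to_numpy(float)
             for a, b in cells_rr])))

    fit = fit_reml(y, X, blocks, beta_names=beta_names)

    mu = fit.fixed("mu")
    year_eff = pd.Series([0.0] + [fit.fixed(f"v_{yr}") for yr in years[1:]],
                         index=years)
    g = pd.Series(fit.blups["g"], index=genos)
    vg = pd.DataFrame(fit.blups["vg"].reshape(len(years), len(genos)).T,
                      index=genos, columns=years)
    s2_vg_year = pd.Series(fit.variances["vg"], index=years)
    s2_g = float(fit.variances["g"][0])
    s2_vg = float(s2_vg_year.mean() if vg_aggregation == "mean"
                  else s2_vg_year.sum())
    denom = s2_vg + s2_g
    pct = 100.0 * s2_vg / denom if denom > 0 else 0.0

    # year-specific (v_j + g_i + vg_ij) vs overall (g_i) rank correlation
    sp = {}
    for yr in years:
        year_pred = year_eff[yr] + g + vg[yr]
        if (np.allclose(vg[yr].to_numpy(), 0.0)
                or np.ptp(year_pred.to_numpy()) == 0 or np.ptp(g.to_numpy()) == 0):
            # no interaction (or no genotype signal at all): no rank changes
            sp[yr] = 1.0
        else:
            sp[yr] = float(spearmanr(year_pred.to_numpy(), g.to_numpy()).statistic)
    return GxEDecomposition(
        mu=mu, year_effects=year_eff, g=g, vg=vg, sigma2_g=s2_g,
        sigma2_vg_by_year=s2_vg_year, sigma2_vg=s2_vg, pct_gxe=float(pct),
        spearman_by_year=pd.Series(sp), sigma2_e=fit.sigma2_e,
        boundary_flags={k: bool(v.any()) for k, v in fit.boundary.items()},
        reml_fit=fit)


def predict_rmse_days(decomp: GxEDecomposition, models,
                      periods: pd.DataFrame, temps_by_year: dict,
                      divisors: pd.Series | None = None) -> float:
    """Calendar-day RMSE of stage-date predictions from the G×E fit.

    The predicted scaled duration for genotype i is mu + g_i + mean_j(v_j)
    (genotype effect plus the mean year effect); it is mapped back to
    compensated units by the genotype's normalization divisor and inverted
    through the year's own temperature course from the observed period
    start.
    """
    res = residual_days(decomp, models, periods, temps_by_year, divisors)
    return float(np.sqrt(np.mean(res["residual_days"].to_numpy() ** 2)))


def residual_days(decomp: GxEDecomposition, models, periods: pd.DataFrame,
                  temps_by_year: dict,
                  divisors: pd.Series | None = None) -> pd.DataFrame:
    """Per-observation calendar-day residuals (predicted − observed t2).

    Predictions use genotype effects plus the mean of year effects; periods
    whose predicted compensated duration is unreachable within the year's
    temperature series are dropped (never imputed).
    """
    _check_period_frame(periods)
    if "y" not in periods.columns:
        raise DataError("periods must carry the compensated duration column 'y'")
    if divisors is None:
        divisors = periods.groupby("cultivar")["y"].mean()
    vbar = float(decomp.year_effects.mean())
    rows = []
    for row in periods.itertuples(index=False):
        model = models[row.cultivar] if isinstance(models, dict) else models
        y_hat = (decomp.mu + decomp.g[row.cultivar] + vbar) * divisors[row.cultivar]
        try:
            t2_hat = invert_compensation(model, temps_by_year[row.year],
                                         row.t1, y_hat)
        except RangeError:
            continue  # threshold beyond the year's series: skip, do not fake
        rows.append({
            "cultivar": row.cultivar, "year": row.year, "rep": row.rep,
            "stage_pair": row.stage_pair,
            "residual_days": (t2_hat - pd.Timestamp(row.t2))
                             / pd.Timedelta(days=1)})
    if not rows:
        raise DataError("no period could be inverted to a calendar date")
    return pd.DataFrame(rows)


def gxe_contrast(periods: pd.DataFrame, model_sets: dict,
                 temps_by_year: dict, *, rmse: bool = True,
                 scaling: str = "rate_unit") -> pd.DataFrame:
    """Compare G×E summaries across response-model choices.

    ``model_sets`` maps a label (e.g. ``thermal_time``, ``cultivar_best``)
    to either a single model or a ``{cultivar: model}`` dict.  The identical
    period table is linearized under every entry; returns one row per label
    with pct_gxe, the Spearman range, and the calendar-day RMSE.
    """
    rows = []
    for label, models in model_sets.items():
        lin = linearize_dataset(models, periods, temps_by_year)
        lin, div = normalize_durations(lin, models, method=scaling)
        dec = fit_gxe_model(lin)
        rec = {"model": label, "pct_gxe": dec.pct_gxe,
               "spearman_min": float(dec.spearman_by_year.min()),
               "spearman_max": float(dec.spearman_by_year.max()),
               "sigma2_g": dec.sigma2_g, "sigma2_vg": dec.sigma2_vg}
        if rmse:
            rec["rmse_days"] = predict_rmse_days(dec, models, lin,
                                                 temps_by_year, div)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("model")


def estimate_jointing_qmer(height: GrowthSeries) -> tuple[pd.Timestamp, str]:
    """Stem-elongation onset by the quarter-of-maximum-elongation-rate rule.

    Takes a (smoothed) plant-height series, computes elongation rates
    between consecutive points, and returns the earliest date at which the
    rate first reaches 25% of its seasonal maximum (linear interpolation
    between interval midpoints), together with a flag: ``"ok"`` or
    ``"degenerate"`` when the rate is constant (QMER undefined, first
    observation returned).
    """
    if len(height) < 3:
        raise DataError("need >= 3 height points")
    t_ns = height.timestamps.asi8.astype(float)
    dt_d = np.diff(t_ns) / 86.4e12
    rates = np.diff(height.values) / dt_d
    rmax = float(rates.max())
    if rmax <= 0:
        raise DataError("height series never increases; QMER undefined")
    if np.allclose(rates, rates[0], rtol=1e-6, atol=1e-12 * max(rmax, 1)):
        return pd.Timestamp(int(t_ns[0])), "degenerate"
    thr = 0.25 * rmax
    mid = (t_ns[:-1] + t_ns[1:]) / 2
    above = np.nonzero(rates >= thr)[0]
    k = int(above[0])
    if k == 0:
        return pd.Timestamp(int(t_ns[0])), "ok"
    frac = (thr - rates[k - 1]) / (rates[k] - rates[k - 1])
    return pd.Timestamp(int(mid[k - 1] + frac * (mid[k] - mid[k - 1]))), "ok"
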