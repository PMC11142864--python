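"""Testing trained response models on unseen growth data.

Growth predictions are scored on *increments* between consecutive
measurements of a series.  Calendar time is first linearized under the
candidate response model, giving a compensated increment r_it per observed
increment dy.  A random-regression mixed model

    dy_ijkt = r_it * (mu + g_i + v_j) + b_j + e_ijkt

is fitted (mu: fixed overall slope; g_i, v_j: random genotype / year slope
deviations; b_j: fixed per-year offset).  Predictions use r_it * mu for
cultivar-level response models (the genotype signal already lives in the
model parameters) and r_it * (mu + g_i) for species-level models and thermal
time, where the random genotype slope supplies the cultivar-specific
intrinsic rate.  Accuracy is reported as the coefficient of determination
against the 1:1 line (which can be negative) and the RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, MetricError, SplitError
from .mixed import RandomBlock, fit_reml

__all__ = [
    "SplitPlan", "RandomRegressionFit", "PredictionMetrics",
    "make_split", "random_regression_test", "r2_1to1", "pool_test_metrics",
]


@dataclass
class SplitPlan:
    mode: str                       # series_ratio | year_cv
    assignments: dict               # unit (series_id or year) -> train|test
    fold: int = 0

    def units(self, role: str) -> list:
        return [u for u, r in self.assignments.items() if r == role]


@dataclass
class PredictionMetrics:
    r2: float
    rmse: float
    n: int
    units: str = ""


@dataclass
class RandomRegressionFit:
    mu: float
    g: pd.Series            # random genotype slope deviations
    v: pd.Series            # random year slope deviations
    b: pd.Series            # fixed year offsets
    variance_components: dict
    predictions: np.ndarray
    metrics: PredictionMetrics
    level: str = "cultivar"
    reml_fit: object = field(default=None, repr=False)


def make_split(data: pd.DataFrame, mode: str, ratio_or_folds=None,
               seed: int = 0):
    """Partition growth data into train/test sets.

    ``mode='series_ratio'`` assigns whole series (one leaf / one plot time
    series never straddles the split) to train or test at the requested
    train:test ratio; returns one :class:`SplitPlan`.  ``mode='year_cv'``
    returns one plan per year, each holding that year out as the test set.
    """
    if mode == "series_ratio":
        if "series_id" not in data.columns:
            raise DataError("series_ratio split needs a series_id column")
        series = sorted(data["series_id"].unique())
        if len(series) < 2:
            raise SplitError("cannot split a single series")
        ratio = 6.37 if ratio_or_folds is None else float(ratio_or_folds)
        n_test = max(int(round(len(series) / (1.0 + ratio))), 1)
        if n_test >= len(series):
            raise SplitError(f"ratio {ratio} leaves no training series")
        rng = np.random.default_rng(seed)
        test = set(rng.choice(series, n_test, replace=False))
        return SplitPlan("series_ratio",
                         {s: ("test" if s in test else "train") for s in series})
    if mode == "year_cv":
        if "year" not in data.columns:
            raise DataError("year_cv split needs a year column")
        years = sorted(data["year"].unique())
        if len(years) < 2:
            raise SplitError("year CV needs >= 2 years")
        return [SplitPlan("year_cv",
                          {y: ("test" if y == held else "train") for y in years},
                          fold=k)
                for k, held in enumerate(years)]
    raise SplitError(f"unknown split mode {mode!r}")


def r2_1to1(observed, predicted) -> PredictionMetrics:
    """R² and RMSE against the 1:1 line (no refitted regression).

    R² = 1 − Σ(obs − pred)² / Σ(obs − mean(obs))²; negative when the
    predictions do worse than the observed mean.  Not clamped.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise DataError("observed/predicted must be equal-length, n >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot <= 0:
        raise MetricError("observed values have zero variance; R² undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return PredictionMetrics(r2=1.0 - ss_res / ss_tot,
                             rmse=float(np.sqrt(np.mean((obs - pred) ** 2))),
                             n=obs.size)


def pool_test_metrics(df: pd.DataFrame, obs_col: str = "observed",
                      pred_col: str = "predicted",
                      group_col: str = "cultivar") -> dict:
    """Per-cultivar 1:1 metrics from pooled test-set predictions.

    Groups with fewer than 2 observations or zero variance are skipped with
    a warning entry (value ``None``).  The key ``"overall"`` pools all rows.
    """
    out = {}
    for g, sub in df.groupby(group_col, sort=True):
        try:
            out[g] = r2_1to1(sub[obs_col], sub[pred_col])
        except (DataError, MetricError):
            out[g] = None
    out["overall"] = r2_1to1(df[obs_col], df[pred_col])
    return out


def random_regression_test(data: pd.DataFrame, level: str = "cultivar"
                           ) -> RandomRegressionFit:
    """Fit the random-regression test model and score predictions.

    ``data`` columns: ``cultivar``, ``year``, ``dy`` (observed increment),
    ``r`` (compensated increment under the response model being tested).
    """
    for c in ("cultivar", "year", "dy", "r"):
        if c not in data.columns:
            raise DataError(f"random regression data lacks column {c!r}")
    genos = sorted(data["cultivar"].unique())
    years = sorted(data["year"].unique())
    if len(genos) < 2 or len(years) < 2:
        raise DataError("need >= 2 genotypes and >= 2 years")

    y = data["dy"].to_numpy(float)
    r = data["r"].to_numpy(float)
    n = len(y)
    Xyear = np.column_stack([(data["year"] == yr).to_numpy(float)
                             for yr in years])
    X = np.column_stack([r, Xyear])
    beta_names = ["mu"] + [f"b_{yr}" for yr in years]
    Zg = np.column_stack([r * (data["cultivar"] == g).to_numpy(float)
                          for g in genos])
    Zv = np.column_stack([r * (data["year"] == yr).to_numpy(float)
                          for yr in years])
    fit = fit_reml(y, X, [RandomBlock("g", Zg, level_names=genos),
                          RandomBlock("v", Zv, level_names=years)],
                   beta_names=beta_names)

    mu = fit.fixed("mu")
    g_blup = pd.Series(fit.blups["g"], index=genos)
    v_blup = pd.Series(fit.blups["v"], index=years)
    b = pd.Series([fit.fixed(f"b_{yr}") for yr in years], index=years)

    if level == "cultivar":
        pred = r * mu
    elif level == "species":
        pred = r * (mu + g_blup.loc[data["cultivar"]].to_numpy())
    else:
        raise DataError(f"unknown level {level!r}")
    metrics = r2_1to1(y, pred)
    vc = {"genotype": float(fit.variances["g"][0]),
          "year": float(fit.variances["v"][0]),
          "residual": fit.sigma2_e}
    return RandomRegressionFit(mu=mu, g=g_blup, v=v_blup, b=b,
                               variance_components=vc, predictions=pred,
                               metrics=metrics, level=level, reml_fit=fit)
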