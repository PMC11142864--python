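"""CSV/YAML readers and writers for all pipeline formats.

Conventions: UTF-8 CSV with '.' decimal separator and ISO 8601 timestamps;
YAML for configuration and model parameters.  Readers validate schemas and
report offending columns; ``write(read(x))`` round-trips.

Formats
-------
temperature CSV   timestamp, temp_c, medium (air|soil), level (plot|reference)
daily weather CSV date, t_mean, t_min, t_max, precip_mm, radiation
growth CSV        cultivar, year, rep, series_id, timestamp, trait, value
phenology CSV     cultivar, year, rep, stage, date
model YAML        cultivar_id -> {kind, <parameters>}; species entry "*"
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dose_response import DoseResponseModel, TemperatureSeries
from .errors import DataError
from .fitting import FitResult, GrowthSeries

__all__ = [
    "read_temperature_csv", "write_temperature_csv",
    "read_weather_csv", "write_weather_csv",
    "read_growth_csv", "write_growth_csv",
    "read_phenology_csv", "write_phenology_csv",
    "read_models_yaml", "write_models_yaml", "write_fit_results",
]


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")


def read_temperature_csv(path) -> TemperatureSeries:
    df = pd.read_csv(path)
    _require(df, ("timestamp", "temp_c", "medium", "level"), path)
    ts = pd.DatetimeIndex(df["timestamp"])
    if not ts.is_monotonic_increasing or ts.has_duplicates:
        bad = np.nonzero(np.diff(ts.asi8) <= 0)[0]
        raise DataError(f"{path}: timestamps out of order near line {bad[0] + 2}")
    medium = df["medium"].iloc[0]
    level = df["level"].iloc[0]
    if (df["medium"] != medium).any() or (df["level"] != level).any():
        raise DataError(f"{path}: mixed medium/level in one file")
    return TemperatureSeries(ts, df["temp_c"].to_numpy(float), medium, level)


def write_temperature_csv(series: TemperatureSeries, path) -> None:
    pd.DataFrame({
        "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
        "temp_c": series.values,
        "medium": series.medium,
        "level": series.level,
    }).to_csv(path, index=False)


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ("date", "t_mean", "t_min", "t_max", "precip_mm", "radiation"),
             path)
    df["date"] = pd.DatetimeIndex(df["date"])
    return df


def write_weather_csv(daily: pd.DataFrame, path) -> None:
    out = daily.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_growth_csv(path) -> list[GrowthSeries]:
    df = pd.read_csv(path)
    _require(df, ("cultivar", "year", "rep", "series_id", "timestamp",
                  "trait", "value"), path)
    df["timestamp"] = pd.DatetimeIndex(df["timestamp"])
    out = []
    for sid, g in df.groupby("series_id", sort=True):
        g = g.sort_values("timestamp")
        out.append(GrowthSeries(
            cultivar_id=str(g["cultivar"].iloc[0]), year=int(g["year"].iloc[0]),
            replication_id=str(g["rep"].iloc[0]), trait=str(g["trait"].iloc[0]),
            timestamps=pd.DatetimeIndex(g["timestamp"]),
            values=g["value"].to_numpy(float), series_id=str(sid)))
    return out


def write_growth_csv(series_list, path) -> None:
    rows = []
    for s in series_list:
        rows.append(pd.DataFrame({
            "cultivar": s.cultivar_id, "year": s.year, "rep": s.replication_id,
            "series_id": s.series_id,
            "timestamp": s.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "trait": s.trait, "value": s.values}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_phenology_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ("cultivar", "year", "rep", "stage", "date"), path)
    df["date"] = pd.DatetimeIndex(df["date"])
    return df


def write_phenology_csv(phenology: pd.DataFrame, path) -> None:
    out = phenology.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_models_yaml(path) -> dict:
    """Model parameter file: ``{cultivar_id: model}``; "*" = species level."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise DataError(f"{path}: expected a mapping cultivar_id -> parameters")
    out = {}
    for cid, params in raw.items():
        if not isinstance(params, dict) or "kind" not in params:
            raise DataError(f"{path}: entry {cid!r} lacks a 'kind'")
        p = dict(params)
        p.setdefault("level", "species" if cid == "*" else "cultivar")
        if cid != "*":
            p.setdefault("cultivar_id", str(cid))
        out[cid] = DoseResponseModel(**p)
    return out


def write_models_yaml(models: dict, path) -> None:
    payload = {cid: m.to_dict() for cid, m in models.items()}
    for d in payload.values():
        d.pop("cultivar_id", None)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def write_fit_results(fits: dict, path, log_path=None) -> None:
    """Serialize FitResults to YAML plus a plain-text fitting log."""
    payload = {}
    lines = []
    for cid, fr in fits.items():
        assert isinstance(fr, FitResult)
        payload[cid] = {
            "model": fr.model.to_dict(), "sigma": float(fr.sigma),
            "ar_order": int(fr.ar_order),
            "ar_coefficients": [float(c) for c in fr.ar_coefficients],
            "log_likelihood": float(fr.log_likelihood), "bic": float(fr.bic),
            "n_obs": int(fr.n_obs), "converged": bool(fr.converged)}
        lines.append(f"{cid}: kind={fr.model.kind} n={fr.n_obs} "
                     f"ar={fr.ar_order} bic={fr.bic:.2f} "
                     f"converged={fr.converged}")
        for p, b in sorted(fr.bic_table.items()):
            lines.append(f"  BIC[ar={p}] = {b:.2f}")
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    if log_path is not None:
        Path(log_path).write_text("\n".join(lines) + "\n")
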