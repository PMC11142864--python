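"""End-to-end pipeline: simulate → fit → validate growth → G×E → indices.

Each stage reads the previous stage's CSV/YAML outputs from the run
directory and writes its own, so stages can be re-run individually (the CLI
exposes them as subcommands).  A :class:`RunManifest` records configuration
hash, seeds, and per-stage outputs; reruns with the same configuration are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .dose_response import DoseResponseModel, compensate_time
from .errors import PhenothermError
from .fitting import fit_tracker_ml
from .indices import build_index_table, lasso_residuals
from .phenology import (fit_gxe_model, gxe_contrast, linearize_dataset,
                        normalize_durations, residual_days)
from .synthetic import ScenarioConfig, Scenario, gen_tracker_series, \
    gen_trait_series, generate_scenario
from .validation import random_regression_test

__all__ = ["RunManifest", "run_pipeline", "STAGES"]

STAGES = ("simulate", "fit", "validate_growth", "phenology_gxe", "env_indices")


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    stages: list = field(default_factory=list)

    def record(self, name: str, outputs: dict, wall_time: float,
               n_records: int) -> None:
        self.stages.append({"stage": name, "outputs": outputs,
                            "wall_time_s": round(wall_time, 3),
                            "n_records": n_records})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _config_hash(config: ScenarioConfig) -> str:
    blob = json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _compensated_increments(model, temps, series):
    comp = compensate_time(model, temps, series.timestamps[0])
    c = np.array([comp.at(d) for d in series.timestamps])
    return np.diff(c)


def run_pipeline(config: ScenarioConfig, out_dir, stages=None) -> RunManifest:
    """Run the configured stages in dependency order.

    Any stage error aborts the run with the stage name in the message.
    """
    out = Path(out_dir)
    stages = list(STAGES) if stages is None else list(stages)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise PhenothermError(f"unknown stages {bad}")
    stages = [s for s in STAGES if s in stages]  # enforce dependency order
    manifest = RunManifest(version="0.1.0", seed=config.seed,
                           config_hash=_config_hash(config))
    scenario: Scenario | None = None

    for stage in stages:
        t0 = time.time()
        try:
            if stage == "simulate":
                scenario, outputs, n = _stage_simulate(config, out)
            else:
                if scenario is None:
                    scenario = generate_scenario(config)
                if stage == "fit":
                    outputs, n = _stage_fit(config, scenario, out)
                elif stage == "validate_growth":
                    outputs, n = _stage_validate(config, scenario, out)
                elif stage == "phenology_gxe":
                    outputs, n = _stage_gxe(config, scenario, out)
                else:
                    outputs, n = _stage_indices(config, scenario, out)
        except PhenothermError as exc:
            raise PhenothermError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, outputs, time.time() - t0, n)

    manifest.save(out / "manifest.yaml")
    return manifest


# ---------------------------------------------------------------------------

def _stage_simulate(config, out):
    scenario = generate_scenario(config)
    wdir = out / "weather"
    gdir = out / "growth"
    pdir = out / "phenology"
    for d in (wdir, gdir, pdir):
        d.mkdir(parents=True, exist_ok=True)
    outputs = {}
    n = 0
    for year in config.years:
        pio.write_temperature_csv(scenario.air_by_year[year],
                                  wdir / f"air_{year}.csv")
        pio.write_temperature_csv(scenario.soil_by_year[year],
                                  wdir / f"soil_{year}.csv")
        pio.write_weather_csv(scenario.daily_by_year[year],
                              wdir / f"daily_{year}.csv")
        n += len(scenario.air_by_year[year])
    trait_series = []
    for year in config.years:
        trait_series += gen_trait_series(scenario.cultivars,
                                         scenario.air_by_year[year],
                                         config, year)
    pio.write_growth_csv(trait_series, gdir / "height.csv")
    tracker = gen_tracker_series(scenario.cultivars,
                                 scenario.air_by_year[config.years[0]], config)
    tracker.to_csv(gdir / "tracker.csv", index=False)
    pio.write_phenology_csv(scenario.phenology, pdir / "stages.csv")
    pio.write_models_yaml(scenario.cultivars, out / "truth_models.yaml")
    scenario.thresholds.to_csv(out / "truth_thresholds.csv")
    outputs = {"weather": str(wdir), "growth": str(gdir),
               "phenology": str(pdir), "truth": str(out / "truth_models.yaml")}
    return scenario, outputs, n + len(tracker) + len(scenario.phenology)


def _stage_fit(config, scenario, out):
    tracker = gen_tracker_series(scenario.cultivars,
                                 scenario.air_by_year[config.years[0]], config)
    fits = fit_tracker_ml(tracker, config.response_kind, level="cultivar")
    species = fit_tracker_ml(tracker, config.response_kind, level="species")
    fits["*"] = species
    pio.write_fit_results(fits, out / "fits.yaml", out / "fits.log")
    models = {cid: fr.model for cid, fr in fits.items()}
    pio.write_models_yaml(models, out / "fitted_models.yaml")
    return ({"fits": str(out / "fits.yaml"),
             "models": str(out / "fitted_models.yaml")},
            sum(f.n_obs for f in fits.values()))


def _load_fitted(out):
    path = out / "fitted_models.yaml"
    if path.exists():
        return pio.read_models_yaml(path)
    return None


def _model_sets(config, scenario, out):
    tt = DoseResponseModel.thermal_time(config.crop)
    sets = {"thermal_time": tt}
    fitted = _load_fitted(out)
    if fitted is not None:
        species = fitted.pop("*", None)
        if species is not None:
            sets["species_fit"] = species
        if fitted:
            sets["cultivar_fit"] = fitted
    else:
        sets["cultivar_true"] = scenario.cultivars
    return sets


def _stage_validate(config, scenario, out):
    sets = _model_sets(config, scenario, out)
    rows = []
    frames = {}
    for year in config.years:
        temps = scenario.air_by_year[year]
        for s in gen_trait_series(scenario.cultivars, temps, config, year):
            dy = np.diff(s.values)
            base = pd.DataFrame({"cultivar": s.cultivar_id, "year": year,
                                 "series_id": s.series_id, "dy": dy})
            for label, models in sets.items():
                m = models[s.cultivar_id] if isinstance(models, dict) else models
                base[f"r_{label}"] = _compensated_increments(m, temps, s)
            frames[s.series_id] = base
    data = pd.concat(frames.values(), ignore_index=True)
    for label, models in sets.items():
        level = "cultivar" if isinstance(models, dict) else "species"
        sub = data.rename(columns={f"r_{label}": "r"})
        fit = random_regression_test(sub, level=level)
        rows.append({"model": label, "level": level,
                     "r2": fit.metrics.r2, "rmse": fit.metrics.rmse,
                     "n": fit.metrics.n, "mu": fit.mu})
    table = pd.DataFrame(rows).set_index("model")
    table.to_csv(out / "growth_metrics.csv")
    return {"metrics": str(out / "growth_metrics.csv")}, len(data)


def _stage_gxe(config, scenario, out):
    sets = _model_sets(config, scenario, out)
    frames = []
    for stage_pair, per in scenario.periods.groupby("stage_pair"):
        tab = gxe_contrast(per, sets, scenario.air_by_year)
        tab.insert(0, "stage_pair", stage_pair)
        frames.append(tab.reset_index())
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out / "gxe_contrast.csv", index=False)

    # residuals (in days) of the cultivar-level model for residual analysis
    best_label = ("cultivar_fit" if "cultivar_fit" in sets
                  else "cultivar_true" if "cultivar_true" in sets
                  else "thermal_time")
    models = sets[best_label]
    res_frames = []
    for stage_pair, per in scenario.periods.groupby("stage_pair"):
        lin = linearize_dataset(models, per, scenario.air_by_year)
        lin, div = normalize_durations(lin, models)
        dec = fit_gxe_model(lin)
        res = residual_days(dec, models, lin, scenario.air_by_year, div)
        res_frames.append(res)
    residuals = pd.concat(res_frames, ignore_index=True)
    residuals.to_csv(out / "phenology_residuals.csv", index=False)
    return ({"contrast": str(out / "gxe_contrast.csv"),
             "residuals": str(out / "phenology_residuals.csv")}, len(table))


def _stage_indices(config, scenario, out):
    res_path = out / "phenology_residuals.csv"
    if res_path.exists():
        residuals = pd.read_csv(res_path)
    else:
        _stage_gxe(config, scenario, out)
        residuals = pd.read_csv(res_path)

    weather = pd.concat(scenario.daily_by_year.values(), ignore_index=True)
    periods_by_year = {}
    for year, per in scenario.periods.groupby("year"):
        periods_by_year[year] = {
            sp: (g["t1"].min().normalize(), g["t2"].max().normalize())
            for sp, g in per.groupby("stage_pair")}
    table = build_index_table(weather, periods_by_year)
    table.to_csv(out / "index_table.csv")

    durations = (scenario.periods.assign(
        dur=(scenario.periods["t2"] - scenario.periods["t1"])
            / pd.Timedelta(days=1))
        .groupby(["cultivar", "stage_pair"])["dur"].mean())

    coef_rows = []
    for stage_pair, res in residuals.groupby("stage_pair"):
        feats = table.xs(stage_pair, level="period").loc[res["year"]]
        feats = feats.reset_index(drop=True)
        feats["mean_duration"] = durations.loc[
            list(zip(res["cultivar"], res["stage_pair"]))].to_numpy()
        att = lasso_residuals(res["residual_days"].to_numpy(), feats,
                              seed=config.seed)
        for name, val in att.selected.items():
            coef_rows.append({"stage_pair": stage_pair, "feature": name,
                              "coefficient": val,
                              "lambda": att.lambda_})
    coefs = pd.DataFrame(coef_rows,
                         columns=["stage_pair", "feature", "coefficient",
                                  "lambda"])
    coefs.to_csv(out / "lasso_coefficients.csv", index=False)
    return ({"indices": str(out / "index_table.csv"),
             "lasso": str(out / "lasso_coefficients.csv")}, len(table))
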