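"""Scoring response models on unseen growth increments.

Compares thermal time, the species-level nonlinear model and the true
cultivar-level models on synthetic multi-year height data using the
random-regression test: predictions from the fixed overall slope (plus the
genotype slope for species-level models), scored against the 1:1 line.
"""

import numpy as np
import pandas as pd

from phenotherm import (DoseResponseModel, ScenarioConfig, compensate_time,
                        random_regression_test, generate_scenario)
from phenotherm.synthetic import gen_trait_series

cfg = ScenarioConfig(seed=5)
sc = generate_scenario(cfg)
model_sets = {
    "thermal_time": DoseResponseModel.thermal_time("wheat"),
    "species": DoseResponseModel("asymptotic", **cfg.species_params),
    "cultivar": sc.cultivars,
}

rows = []
for year in cfg.years:
    temps = sc.air_by_year[year]
    for s in gen_trait_series(sc.cultivars, temps, cfg, year):
        rec = pd.DataFrame({"cultivar": s.cultivar_id, "year": year,
                            "dy": np.diff(s.values)})
        for label, models in model_sets.items():
            m = models[s.cultivar_id] if isinstance(models, dict) else models
            comp = compensate_time(m, temps, s.timestamps[0])
            c = np.array([comp.at(d) for d in s.timestamps])
            rec[f"r_{label}"] = np.diff(c)
        rows.append(rec)
data = pd.concat(rows, ignore_index=True)

print(f"{len(data)} height increments, 12 cultivars x 6 years x 2 reps\n")
print(f"{'model':<14}{'level':<10}{'R2':>7}{'RMSE mm':>9}")
for label, models in model_sets.items():
    level = "cultivar" if isinstance(models, dict) else "species"
    fit = random_regression_test(data.rename(columns={f"r_{label}": "r"}),
                                 level=level)
    print(f"{label:<14}{level:<10}{fit.metrics.r2:>7.3f}"
          f"{fit.metrics.rmse:>9.1f}")
print("\nCultivar-level compensation explains the most increment variance; "
      "thermal time needs the genotype scaling slope and still trails the "
      "nonlinear models.")
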