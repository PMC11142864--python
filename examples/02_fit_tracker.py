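"""Fitting a nonlinear response to dense leaf-tracker rates.

Generates one season of minutes-scale growth rates with AR(1) measurement
noise from a known asymptotic response and recovers its parameters by
exact maximum likelihood, selecting the residual autocorrelation order by
BIC.
"""

from phenotherm import ScenarioConfig, fit_tracker_ml
from phenotherm.synthetic import gen_cultivars, gen_tracker_series, gen_weather

cfg = ScenarioConfig(seed=4, n_cultivars=1,
                     species_params={"T_min": 1.0, "r_max": 1.5, "s": -2.0},
                     cultivar_sd={"r_max": 0.0, "T_min": 0.0, "s": 0.0},
                     tracker_ar=(0.6,), tracker_sigma=0.2,
                     tracker_cadence_min=10)
truth = gen_cultivars(cfg)["cv01"]
air, _, _ = gen_weather(cfg, 2019)
rates = gen_tracker_series(truth and {"cv01": truth}, air, cfg, n_series=2)

fit = fit_tracker_ml(rates, "asymptotic", level="species")
m = fit.model
print(f"n = {fit.n_obs} rate/temperature pairs")
print(f"true:      T_min={truth.T_min:.2f}  r_max={truth.r_max:.3f}  "
      f"s={truth.s:.2f}, AR(1) phi=0.6 sigma=0.2")
print(f"recovered: T_min={m.T_min:.2f}  r_max={m.r_max:.3f}  s={m.s:.2f}, "
      f"AR({fit.ar_order}) phi={fit.ar_coefficients.round(2)} "
      f"sigma={fit.sigma:.3f}")
print("BIC per autocorrelation order:",
      {p: round(b, 1) for p, b in fit.bic_table.items()})
print("The BIC-minimal order matches the generating AR(1) noise; the "
      "cardinal parameters are recovered without smoothing the raw rates.")
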