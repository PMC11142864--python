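"""Temperature response curves and compensated ("linearized") time.

Builds the four parametric response families, accumulates compensated time
over a diurnal temperature course, and inverts the integral back to a
calendar instant.
"""

import numpy as np
import pandas as pd

from phenotherm import (DoseResponseModel, TemperatureSeries,
                        compensate_time, eval_response, invert_compensation)

models = {
    "thermal time (wheat)": DoseResponseModel.thermal_time("wheat"),
    "bilinear": DoseResponseModel("bilinear", T_min=3.0, a=0.9, r_min=1.5),
    "asymptotic": DoseResponseModel("asymptotic", T_min=1.0, r_max=12.0,
                                    s=-2.0),
    "Wang-Engel": DoseResponseModel("wang_engel", T_min=0.0, T_opt=22.0,
                                    T_max=33.0, r_max=12.0),
}

print("response rate at selected temperatures (units: trait per hour)")
temps_c = [0.0, 5.0, 15.0, 22.0, 30.0]
print(f"{'model':<22}" + "".join(f"{t:>8.0f}C" for t in temps_c))
for name, m in models.items():
    rates = eval_response(m, np.array(temps_c))
    print(f"{name:<22}" + "".join(f"{r:>9.2f}" for r in rates))

# five days of a 12 +/- 8 degC diurnal course, hourly
ts = pd.date_range("2021-04-01", periods=121, freq="h")
course = TemperatureSeries(ts, 12 + 8 * np.sin(2 * np.pi
                                               * (np.arange(121) - 9) / 24))
tt = models["thermal time (wheat)"]
comp = compensate_time(tt, course)
print(f"\nthermal time accumulated over 5 diurnal days: "
      f"{comp.total:.1f} degC*d")
target = 30.0
when = invert_compensation(tt, course, ts[0], target)
print(f"{target:.0f} degC*d is reached at {when} — the calendar instant a "
      "development threshold of 30 degree-days would be crossed.")
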