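import warnings

import numpy as np
import pandas as pd
import pytest

from phenotherm import (DoseResponseModel, ScenarioConfig, TemperatureSeries,
                        generate_scenario)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def wheat_tt():
    return DoseResponseModel.thermal_time("wheat")


@pytest.fixture(scope="session")
def wang_engel():
    return DoseResponseModel("wang_engel", T_min=0.0, T_opt=20.0,
                             T_max=35.0, r_max=1.0)


@pytest.fixture
def constant_temps():
    """48 hours at a constant 15 °C."""
    ts = pd.date_range("2020-01-01", periods=49, freq="h")
    return TemperatureSeries(ts, np.full(49, 15.0))


@pytest.fixture
def diurnal_temps():
    """Ten days of a 12 ± 8 °C diurnal sinusoid, hourly."""
    ts = pd.date_range("2020-04-01", periods=240, freq="h")
    hours = np.arange(240)
    return TemperatureSeries(ts, 12 + 8 * np.sin(2 * np.pi * (hours - 9) / 24))


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced wheat scenario shared by the slower integration tests."""
    cfg = ScenarioConfig(seed=11, n_cultivars=6, n_years=4, n_reps=2)
    return generate_scenario(cfg)
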