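"""Shared fixtures: tiny constructed weather series and synthetic datasets."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from thermaltime.gdd import ThermalThresholds
from thermaltime.synthetic import VirtualCultivar, WeatherScenario, generate_dataset
from thermaltime.weather_io import HourlyTemperatureSeries


def make_series(
    temps, start: str = "2005-03-01", site_label: str = "test"
) -> HourlyTemperatureSeries:
    """Series from an explicit list/array of hourly temperatures."""
    temps = np.asarray(temps, dtype=float)
    idx = pd.date_range(start, periods=len(temps), freq="h")
    return HourlyTemperatureSeries(site_label=site_label, data=pd.Series(temps, index=idx))


def constant_series(
    temp: float, days: int, start: str = "2005-03-01", site_label: str = "const"
) -> HourlyTemperatureSeries:
    return make_series(np.full(days * 24, temp), start=start, site_label=site_label)


@pytest.fixture
def thresholds_5_30() -> ThermalThresholds:
    return ThermalThresholds(t_base=5.0, t_upper=30.0)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Five noiseless synthetic seasons from the default cultivar (truth 5/30)."""
    return generate_dataset(WeatherScenario(noise_sd=0.0, seed=11), VirtualCultivar())


@pytest.fixture(scope="session")
def random_series_30d():
    """Seeded random 30-day hourly series for oracle-equivalence checks."""
    rng = np.random.default_rng(42)
    out = []
    for k in range(5):
        temps = rng.uniform(-5.0, 45.0, size=30 * 24)
        out.append(make_series(temps, start=f"200{k}-04-01", site_label=f"rand{k}"))
    return out
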