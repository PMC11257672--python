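import numpy as np
import pandas as pd
import pytest

from raincross.core import LocationSeries
from raincross.synthetic import (
    WEATHER_PRESETS,
    climate_truth,
    simulate_study,
    simulate_weather,
    simulate_deaths,
)


def make_location(
    climate: str = "tropical",
    years: float = 2.0,
    seed: int = 42,
    truth=None,
    location_id: str = "loc001",
    country: str = "country01",
) -> LocationSeries:
    """Single synthetic location with its climate's default (or given) truth."""
    n_days = int(round(years * 365.25))
    truth = truth or climate_truth(climate)
    precip, temp = simulate_weather(WEATHER_PRESETS[climate], n_days, seed)
    deaths, _ = simulate_deaths(precip, temp, truth, seed=seed + 1)
    dates = pd.date_range("2008-01-01", periods=n_days, freq="D")
    return LocationSeries(
        location_id,
        country,
        climate,
        pd.DataFrame({"date": dates, "deaths": deaths, "precip_mm": precip, "temp_c": temp}),
    )


@pytest.fixture(scope="session")
def small_study():
    """4 countries x 2 locations, 3 years: fast but exercises all climates."""
    assignment = {
        "country01": ("tropical", "arid"),
        "country02": ("temperate", "tropical"),
        "country03": ("arid", "temperate"),
        "country04": ("tropical", "temperate"),
    }
    locs, sidecar = simulate_study(
        climate_assignment=assignment, years=3, seed=2024, country_sd=0.03
    )
    return locs, sidecar


@pytest.fixture(scope="session")
def two_year_location():
    return make_location("tropical", years=2.0, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
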