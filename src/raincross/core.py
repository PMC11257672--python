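"""Core data containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLIMATES = ("tropical", "arid", "temperate")

#: Köppen first-level letter -> first-level climate zone. Cold (D) and polar (E)
#: sub-climates are outside the study domain and are rejected on sight.
KOPPEN_FIRST_LEVEL = {"A": "tropical", "B": "arid", "C": "temperate"}

STANDARD_COLUMNS = ["location_id", "country", "climate", "date", "deaths", "precip_mm", "temp_c"]


@dataclass
class LocationSeries:
    """One within-country climatic region's daily series: the unit of first-stage analysis."""

    location_id: str
    country: str
    climate: str
    data: pd.DataFrame  # columns: date, deaths, precip_mm, temp_c

    def __post_init__(self) -> None:
        if self.climate not in CLIMATES:
            raise ValueError(f"unknown climate {self.climate!r}; expected one of {CLIMATES}")
        required = {"date", "deaths", "precip_mm", "temp_c"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"location series missing columns: {sorted(missing)}")

    @property
    def n_days(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["date"])

    @property
    def deaths(self) -> np.ndarray:
        return self.data["deaths"].to_numpy()

    @property
    def precip(self) -> np.ndarray:
        return self.data["precip_mm"].to_numpy(dtype=float)

    @property
    def temp(self) -> np.ndarray:
        return self.data["temp_c"].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "location_id", self.location_id)
        out.insert(1, "country", self.country)
        out.insert(2, "climate", self.climate)
        return out[STANDARD_COLUMNS]


def study_to_frame(locations: list[LocationSeries]) -> pd.DataFrame:
    """Concatenate locations into the standard long input table."""
    return pd.concat([loc.to_frame() for loc in locations], ignore_index=True)


def study_from_frame(df: pd.DataFrame) -> list[LocationSeries]:
    """Split the standard long table back into per-location series."""
    missing = set(STANDARD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"input table missing columns: {sorted(missing)}")
    out = []
    for loc_id, g in df.groupby("location_id", sort=True):
        g = g.sort_values("date").reset_index(drop=True)
        country = g["country"].iloc[0]
        climate = g["climate"].iloc[0]
        if (g["country"] != country).any() or (g["climate"] != climate).any():
            raise ValueError(f"location {loc_id!r} has inconsistent country/climate metadata")
        data = g[["date", "deaths", "precip_mm", "temp_c"]].copy()
        data["date"] = pd.to_datetime(data["date"])
        out.append(LocationSeries(str(loc_id), str(country), str(climate), data))
    return out
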