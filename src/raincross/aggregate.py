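"""Aggregation of subnational-unit series into within-country climatic regions.

Units (the smallest administrative level with death counts and
population-weighted weather) are grouped by country and Köppen
sub-climate: deaths are summed per day, weather is averaged across units
using each unit's whole-period death total as a time-constant weight, and
the region inherits the first-level climate zone of its sub-climate
letter (A tropical, B arid, C temperate; cold/polar D and E are outside
the study domain).  Regions are then screened by the inclusion rule: at
least one death in every calendar month of the region's span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import KOPPEN_FIRST_LEVEL, LocationSeries

__all__ = [
    "UnitSeries",
    "weighted_weather",
    "assign_climate",
    "build_regions",
    "filter_regions",
]


@dataclass
class UnitSeries:
    """One subnational unit's daily series plus its Köppen sub-climate label."""

    unit_id: str
    country: str
    sub_climate: str  # third-level Köppen label, e.g. "Af", "BWh", "Cfb"
    population_weight: float
    data: pd.DataFrame  # columns: date, deaths, precip_mm, temp_c

    def __post_init__(self) -> None:
        if self.population_weight <= 0:
            raise ValueError("population_weight must be > 0")
        letter = self.sub_climate[:1].upper()
        if letter not in KOPPEN_FIRST_LEVEL:
            raise ValueError(
                f"sub-climate {self.sub_climate!r}: first-level zone {letter!r} is "
                "outside the study domain (only A/B/C, i.e. tropical/arid/temperate)"
            )

    @property
    def climate(self) -> str:
        return KOPPEN_FIRST_LEVEL[self.sub_climate[:1].upper()]


def weighted_weather(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted arithmetic mean across units, per day.

    ``values`` has shape (n_units, n_days); ``weights`` length n_units.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    return (weights[:, None] * values).sum(axis=0) / total


def assign_climate(sub_counts: dict[str, float]) -> str:
    """Sub-climate label with the greatest population total; ties go lexicographic."""
    if not sub_counts:
        raise ValueError("empty sub-climate population map")
    best = max(sub_counts.values())
    winners = sorted(k for k, v in sub_counts.items() if v == best)
    if len(winners) > 1:
        warnings.warn(
            f"population tie between sub-climates {winners}: choosing {winners[0]}",
            stacklevel=2,
        )
    return winners[0]


def build_regions(units: list[UnitSeries]) -> list[LocationSeries]:
    """Combine units into (country, sub-climate) regions.

    Deaths are summed per day; weather is averaged across units weighted by
    each unit's total diarrheal deaths over the whole period (units that
    recorded no deaths get zero weight; if a whole region has none, weights
    fall back to equal).
    """
    if not units:
        return []
    cal = pd.DatetimeIndex(units[0].data["date"])
    for u in units[1:]:
        if not cal.equals(pd.DatetimeIndex(u.data["date"])):
            raise ValueError(f"unit {u.unit_id!r} is on a different calendar")
    groups: dict[tuple[str, str], list[UnitSeries]] = {}
    for u in units:
        groups.setdefault((u.country, u.sub_climate), []).append(u)
    out = []
    for (country, sub), members in sorted(groups.items()):
        deaths = np.vstack([m.data["deaths"].to_numpy(dtype=float) for m in members])
        precip = np.vstack([m.data["precip_mm"].to_numpy(dtype=float) for m in members])
        temp = np.vstack([m.data["temp_c"].to_numpy(dtype=float) for m in members])
        w = deaths.sum(axis=1)
        if w.sum() == 0:
            w = np.ones(len(members))
        data = pd.DataFrame(
            {
                "date": cal,
                "deaths": deaths.sum(axis=0).astype(int),
                "precip_mm": weighted_weather(precip, w),
                "temp_c": weighted_weather(temp, w),
            }
        )
        out.append(
            LocationSeries(
                location_id=f"{country}_{sub}",
                country=country,
                climate=KOPPEN_FIRST_LEVEL[sub[:1].upper()],
                data=data,
            )
        )
    return out


def filter_regions(
    regions: list[LocationSeries],
) -> tuple[list[LocationSeries], list[dict]]:
    """Keep regions with at least one death in every calendar month of their span.

    Returns the included regions and an exclusion report naming each
    excluded region's first zero-death month.
    """
    included = []
    report = []
    for r in regions:
        monthly = (
            r.data.assign(_ym=pd.DatetimeIndex(r.data["date"]).strftime("%Y-%m"))
            .groupby("_ym")["deaths"]
            .sum()
        )
        zero = monthly[monthly == 0]
        if len(zero) == 0:
            included.append(r)
        else:
            report.append(
                {
                    "location_id": r.location_id,
                    "first_zero_month": zero.index[0],
                    "n_zero_months": int(len(zero)),
                }
            )
    return included, report
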