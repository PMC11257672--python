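"""Pipeline orchestration: configuration, IO, full run and sensitivity suite.

The standard input is a delimited table (UTF-8, comma-separated,
ISO-8601 dates) with columns ``location_id, country, climate, date,
deaths, precip_mm, temp_c``.  ``run_pipeline`` applies the inclusion
filter, fits the first-stage case-crossover model per location, pools the
precipitation-spline coefficients by climate with the multilevel
meta-regression, and emits risk summaries (pooled per climate and BLUP
per country-climate) plus a manifest that suffices to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .casecrossover import StageOneFit, StratumScheme, fit_location, percentile_table
from .core import CLIMATES, LocationSeries, study_from_frame
from .meta import MetaFit, pool
from .risk import climate_summary
from .splines import percentile_knots, running_sum

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "run_sensitivity_suite",
    "filter_regions",
    "write_bundle",
    "read_table",
    "write_table",
]

# inclusion filter lives with the aggregation logic but is part of the
# standard pipeline entry, so re-export it here
from .aggregate import filter_regions  # noqa: E402


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable settings of the two-stage analysis."""

    window_days: int = 28
    precip_knot_percentiles: tuple[float, ...] = (50.0, 90.0)
    temp_knot_percentiles: tuple[float, ...] = (33.0, 67.0)
    max_lag: int = 28
    n_lag_knots: int = 3
    stratum: StratumScheme = field(default_factory=StratumScheme)
    include_month_indicator: bool = True
    meta_predictor: str | None = None
    knot_sharing: str = "per_climate"  # or "per_location"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_days not in (7, 14, 21, 28):
            warnings.warn(
                f"window_days={self.window_days} is outside the standard set "
                "{7, 14, 21, 28}",
                stacklevel=2,
            )
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.knot_sharing not in ("per_climate", "per_location"):
            raise ValueError("knot_sharing must be 'per_climate' or 'per_location'")

    def to_dict(self) -> dict:
        return {
            "window_days": self.window_days,
            "precip_knot_percentiles": list(self.precip_knot_percentiles),
            "temp_knot_percentiles": list(self.temp_knot_percentiles),
            "max_lag": self.max_lag,
            "n_lag_knots": self.n_lag_knots,
            "stratum": self.stratum.to_dict(),
            "include_month_indicator": self.include_month_indicator,
            "meta_predictor": self.meta_predictor,
            "knot_sharing": self.knot_sharing,
            "seed": self.seed,
        }


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"], float_precision="round_trip")


def write_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.17g")


def _usable_cum(loc: LocationSeries, config: PipelineConfig) -> np.ndarray:
    cum = running_sum(loc.precip, config.window_days)
    start = max(config.window_days, config.max_lag)
    cum[:start] = np.nan
    return cum[np.isfinite(cum)]


def _climate_tables(
    locations: list[LocationSeries], config: PipelineConfig
) -> tuple[dict, dict]:
    """Pooled usable-day exposure percentile tables and common specs per climate.

    Pooling concatenates usable-day running sums across the climate's
    locations, so each location contributes in proportion to its person-days.
    """
    pooled: dict[str, list[np.ndarray]] = {}
    for loc in locations:
        pooled.setdefault(loc.climate, []).append(_usable_cum(loc, config))
    tables = {}
    specs = {}
    for climate, chunks in pooled.items():
        allv = np.concatenate(chunks)
        tables[climate] = percentile_table(allv)
        specs[climate] = percentile_knots(allv, list(config.precip_knot_percentiles))
    return tables, specs


def run_pipeline(
    data: pd.DataFrame | list[LocationSeries],
    config: PipelineConfig | None = None,
    meta_predictors: dict[str, dict[str, float]] | None = None,
) -> dict:
    """Full two-stage run: filter -> per-location fits -> pooling -> risk summaries.

    ``meta_predictors`` optionally maps location_id -> {name: value} for
    second-stage continuous meta-predictors.  Per-location failures are
    isolated: the location is excluded from pooling and recorded in the
    manifest.
    """
    config = config or PipelineConfig()
    locations = study_from_frame(data) if isinstance(data, pd.DataFrame) else list(data)
    included, exclusion_report = filter_regions(locations)
    if not included:
        raise ValueError("no locations pass the inclusion filter")

    climate_pcts, climate_specs = _climate_tables(included, config)

    fits: list[StageOneFit] = []
    failures = []
    logs = []
    for loc in included:
        spec = (
            climate_specs[loc.climate] if config.knot_sharing == "per_climate" else None
        )
        mp = (meta_predictors or {}).get(loc.location_id, {})
        try:
            f = fit_location(
                loc,
                window=config.window_days,
                scheme=config.stratum,
                precip_spec=spec,
                precip_knot_percentiles=config.precip_knot_percentiles,
                temp_knot_percentiles=config.temp_knot_percentiles,
                max_lag=config.max_lag,
                n_lag_knots=config.n_lag_knots,
                include_month_indicator=config.include_month_indicator,
                meta_predictors=mp,
            )
        except Exception as e:  # noqa: BLE001 - per-location isolation
            failures.append({"location_id": loc.location_id, "error": str(e)})
            warnings.warn(
                f"location {loc.location_id} failed to fit and is excluded: {e}",
                stacklevel=2,
            )
            continue
        fits.append(f)
        logs.append(
            {
                "location_id": loc.location_id,
                "climate": loc.climate,
                "country": loc.country,
                "n_strata_used": f.n_strata_used,
                "n_days_used": f.n_days_used,
                "dispersion": f.dispersion,
            }
        )
    if len(fits) < 2:
        raise ValueError("fewer than 2 locations fitted successfully; cannot pool")

    metafit = pool(fits, meta_predictor=config.meta_predictor)

    risk = {}
    for climate in (c for c in CLIMATES if c in metafit.climate_levels):
        coef, vcov = metafit.climate_coef(climate)
        risk[climate] = climate_summary(
            coef,
            vcov,
            climate_specs[climate],
            climate_pcts[climate],
            source="pooled_climate",
        )

    # BLUP country-climate curves: BLUP coefficients are shared within a
    # country; the exposure distribution is the country's own.
    risk_blup = {}
    by_cc: dict[tuple[str, str], list[StageOneFit]] = {}
    for f in fits:
        by_cc.setdefault((f.country, f.climate), []).append(f)
    loc_by_id = {loc.location_id: loc for loc in included}
    for (country, climate), members in sorted(by_cc.items()):
        b = metafit.blups[members[0].location_id]
        coef = np.asarray(b["coef"])
        vcov = np.asarray(b["vcov"])
        cc_cum = np.concatenate(
            [_usable_cum(loc_by_id[f.location_id], config) for f in members]
        )
        pcts = percentile_table(cc_cum)
        risk_blup[f"{country}|{climate}"] = climate_summary(
            coef, vcov, climate_specs[climate], pcts, source="blup_country_climate"
        )

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_locations_input": len(locations),
        "n_locations_included": len(included),
        "n_locations_fitted": len(fits),
        "exclusions_filter": exclusion_report,
        "fit_failures": failures,
        "locations": logs,
        "psi_structure": metafit.psi_structure,
        "meta_converged": metafit.converged,
    }
    return {
        "manifest": manifest,
        "stage1": fits,
        "meta": metafit,
        "risk": risk,
        "risk_blup": risk_blup,
        "climate_percentiles": climate_pcts,
        "climate_specs": climate_specs,
    }


def _summary_entry(s: dict) -> dict:
    return {
        "mmp_mm": s["mmp_mm"],
        "mmp_percentile": s["mmp_percentile"],
        "pct_change_dry": {
            k: s["pct_change_dry"][k] for k in ("mm", "pct_change", "ci_low", "ci_high")
        },
        "pct_change_wet": {
            k: s["pct_change_wet"][k] for k in ("mm", "pct_change", "ci_low", "ci_high")
        },
        "source": s["source"],
    }


def bundle_summary(bundle: dict) -> dict:
    """JSON-serializable summary of a pipeline run (deterministic key order)."""
    meta: MetaFit = bundle["meta"]
    return {
        "manifest": bundle["manifest"],
        "meta": meta.to_dict(),
        "stage1": [f.to_dict() for f in bundle["stage1"]],
        "risk": {c: _summary_entry(s) for c, s in sorted(bundle["risk"].items())},
        "risk_blup": {
            c: _summary_entry(s) for c, s in sorted(bundle["risk_blup"].items())
        },
    }


def write_bundle(bundle: dict, outdir) -> None:
    """Write summary JSON plus tidy curve tables under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(bundle_summary(bundle), fh, indent=1, sort_keys=True)
        fh.write("\n")
    for key, sub in (("risk", "curve_pooled"), ("risk_blup", "curve_blup")):
        for name, s in sorted(bundle[key].items()):
            safe = name.replace("|", "_")
            s["curve"].to_table().to_csv(
                outdir / f"{sub}_{safe}.csv", index=False, float_format="%.15g"
            )


def run_sensitivity_suite(
    data: pd.DataFrame | list[LocationSeries],
    base_config: PipelineConfig | None = None,
    meta_predictors: dict[str, dict[str, float]] | None = None,
    meta_predictor_names: list[str] | None = None,
) -> dict:
    """Base run plus the five sensitivity families, each isolated.

    1. quarterly strata shifted to start in February / March;
    2. year x month x weekday strata (month indicator removed);
    3. running-sum windows of 7, 14 and 21 days;
    4. month indicator removed;
    5. each continuous meta-predictor added singly to the second stage.
    """
    base_config = base_config or PipelineConfig()
    variants: dict[str, PipelineConfig] = {}
    for off in (1, 2):
        variants[f"quarter_offset_{off}"] = replace(
            base_config, stratum=StratumScheme("quarter_dow", off)
        )
    variants["month_strata"] = replace(
        base_config,
        stratum=StratumScheme("month_dow", 0),
        include_month_indicator=False,
    )
    for w in (7, 14, 21):
        variants[f"window_{w}"] = replace(base_config, window_days=w)
    variants["no_month_indicator"] = replace(base_config, include_month_indicator=False)
    for name in meta_predictor_names or []:
        variants[f"meta_predictor_{name}"] = replace(base_config, meta_predictor=name)

    out = {"base": run_pipeline(data, base_config, meta_predictors), "variants": {}}
    for name, cfg in variants.items():
        try:
            out["variants"][name] = run_pipeline(data, cfg, meta_predictors)
        except Exception as e:  # noqa: BLE001 - per-variant isolation
            out["variants"][name] = {"error": str(e)}
    return out
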