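"""Exposure-response summaries: RR curves, minimum-risk precipitation, % changes.

Pooled (or BLUP) spline coefficients are turned into relative-risk curves
by contrasting the basis at each grid point against the basis at a
reference exposure: ``log RR(x) = [b(x) - b(ref)]' beta`` with standard
error ``sqrt(c' V c)`` and normal 95% intervals.  The minimum-risk
precipitation (MMP) is the argmin of the curve over the interval from the
minimum observed exposure to its 90th percentile, and headline summaries
are the percentage change in risk at the 5th ("extremely dry") and 95th
("extremely wet") percentiles relative to the MMP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .splines import SplineSpec, _ns_design

__all__ = [
    "RiskCurve",
    "predict_curve",
    "find_mmp",
    "pct_change_at",
    "percentile_to_mm",
    "climate_summary",
]

Z95 = 1.959963984540054  # standard normal 97.5% quantile


def percentile_to_mm(percentiles: dict[str, float], pct: float) -> float:
    """Exposure value (mm) at a percentile of a recorded distribution table.

    The table carries ``min`` (percentile 0), ``p1``..``p99`` and ``max``
    (percentile 100); intermediate percentiles interpolate linearly.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {pct}")
    xs = np.arange(0, 101, dtype=float)
    ys = [percentiles["min"]] + [percentiles[f"p{i}"] for i in range(1, 100)] + [
        percentiles["max"]
    ]
    return float(np.interp(pct, xs, ys))


@dataclass
class RiskCurve:
    """RR curve on a precipitation grid, centered so log RR(reference) = 0."""

    grid: np.ndarray  # mm (28-day sums)
    log_rr: np.ndarray
    se_log_rr: np.ndarray
    reference: float  # mm
    coef: np.ndarray
    vcov: np.ndarray
    spec: SplineSpec
    percentiles: dict[str, float] | None = None
    mmp: dict | None = None  # {"mm", "percentile"}
    source: str = "pooled_climate"
    grid_percentile: np.ndarray | None = None

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.log_rr - Z95 * self.se_log_rr)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.log_rr + Z95 * self.se_log_rr)

    def to_table(self):
        import pandas as pd

        d = {
            "grid_mm": self.grid,
            "rr": self.rr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }
        if self.grid_percentile is not None:
            d = {"percentile": self.grid_percentile, **d}
        return pd.DataFrame(d)


def _contrast(spec: SplineSpec, x: np.ndarray, reference: float) -> np.ndarray:
    B = _ns_design(np.asarray(x, dtype=float), spec)
    Bref = _ns_design(np.asarray([reference], dtype=float), spec)
    return B - Bref


def predict_curve(
    coef: np.ndarray,
    vcov: np.ndarray,
    spec: SplineSpec,
    grid: np.ndarray,
    reference: float,
    percentiles: dict[str, float] | None = None,
    source: str = "pooled_climate",
    grid_percentile: np.ndarray | None = None,
) -> RiskCurve:
    """RR with CI at each grid point relative to the reference exposure."""
    coef = np.asarray(coef, dtype=float)
    vcov = np.asarray(vcov, dtype=float)
    if np.linalg.eigvalsh((vcov + vcov.T) / 2).min() < -1e-8:
        raise ValueError("coefficient covariance is not positive semidefinite")
    grid = np.asarray(grid, dtype=float)
    lo, hi = spec.boundary_knots
    if (grid < lo - 1e-9).any() or (grid > hi + 1e-9).any():
        warnings.warn(
            "grid extends beyond the spline boundary knots: linear extrapolation",
            stacklevel=2,
        )
    C = _contrast(spec, grid, reference)
    log_rr = C @ coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, vcov, C), 0.0))
    return RiskCurve(
        grid=grid,
        log_rr=log_rr,
        se_log_rr=se,
        reference=float(reference),
        coef=coef,
        vcov=vcov,
        spec=spec,
        percentiles=percentiles,
        source=source,
        grid_percentile=grid_percentile,
    )


def find_mmp(
    coef: np.ndarray,
    spec: SplineSpec,
    percentiles: dict[str, float],
    search_upper_pct: float = 90.0,
) -> dict:
    """Minimum-risk precipitation: argmin of log RR between min and the 90th pct.

    Searched on a 1-percentile grid, refined to 0.1 percentile around the
    coarse argmin; ties break toward the smaller precipitation value.
    """
    coef = np.asarray(coef, dtype=float)

    def log_rr_at(pcts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mm = np.array([percentile_to_mm(percentiles, p) for p in pcts])
        ref = percentiles["min"]
        return _contrast(spec, mm, ref) @ coef, mm

    coarse = np.arange(0.0, search_upper_pct + 0.5, 1.0)
    vals, mms = log_rr_at(coarse)
    i = int(np.argmin(np.round(vals, 12)))  # first minimum -> smaller mm on ties
    lo = max(0.0, coarse[i] - 1.0)
    hi = min(search_upper_pct, coarse[i] + 1.0)
    fine = np.arange(lo, hi + 0.05, 0.1)
    fvals, fmms = log_rr_at(fine)
    j = int(np.argmin(np.round(fvals, 12)))
    if fvals[j] > vals[i]:  # refinement never worsens the coarse optimum
        j_mm, j_pct = mms[i], coarse[i]
    else:
        j_mm, j_pct = fmms[j], fine[j]
    return {"mm": float(j_mm), "percentile": float(j_pct)}


def pct_change_at(curve: RiskCurve, percentile: float) -> dict:
    """Percent change in risk at a precipitation percentile vs the curve reference.

    The curve must be centered at the minimum-risk precipitation for the
    headline "extremely dry (5th)" / "extremely wet (95th)" summaries.
    Returns the point estimate and 95% CI, all in percent.
    """
    if curve.percentiles is None:
        raise ValueError("curve carries no percentile table")
    mm = percentile_to_mm(curve.percentiles, percentile)
    C = _contrast(curve.spec, np.array([mm]), curve.reference)
    lr = (C @ curve.coef).item()
    se = float(np.sqrt(max((C @ curve.vcov @ C.T).item(), 0.0)))
    return {
        "percentile": float(percentile),
        "mm": mm,
        "pct_change": (np.exp(lr) - 1.0) * 100.0,
        "ci_low": (np.exp(lr - Z95 * se) - 1.0) * 100.0,
        "ci_high": (np.exp(lr + Z95 * se) - 1.0) * 100.0,
    }


def climate_summary(
    coef: np.ndarray,
    vcov: np.ndarray,
    spec: SplineSpec,
    percentiles: dict[str, float],
    source: str = "pooled_climate",
    n_grid: int = 100,
) -> dict:
    """Full risk summary for one coefficient vector: curve + MMP + 5th/95th changes.

    The curve is reported on a percentile-spaced grid (plus the exact 5th,
    50th and 95th percentile points), centered at the MMP.
    """
    mmp = find_mmp(coef, spec, percentiles)
    pcts = np.unique(np.concatenate([np.linspace(0, 100, n_grid), [5.0, 50.0, 95.0]]))
    grid = np.array([percentile_to_mm(percentiles, p) for p in pcts])
    curve = predict_curve(
        coef,
        vcov,
        spec,
        grid,
        reference=mmp["mm"],
        percentiles=percentiles,
        source=source,
        grid_percentile=pcts,
    )
    curve.mmp = mmp
    dry = pct_change_at(curve, 5.0)
    wet = pct_change_at(curve, 95.0)
    return {
        "curve": curve,
        "mmp_mm": mmp["mm"],
        "mmp_percentile": mmp["percentile"],
        "pct_change_dry": dry,
        "pct_change_wet": wet,
        "source": source,
    }
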