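"""Design-matrix building blocks for the first-stage model.

The per-location model regresses daily death counts on

* a natural cubic spline of the running sum of precipitation over the
  prior ``window`` days (the cumulative-precipitation exposure),
* a bidimensional (exposure x lag) natural-spline cross-basis of daily
  mean temperature over lags 0..28, and
* calendar-month indicator columns,

with stratum intercepts handled by the conditional fitter.  This module
builds each of those blocks.  Natural cubic splines are constructed from
a cubic B-spline basis with the two second-derivative-at-boundary
constraints removed via a QR projection, and are extended linearly
beyond the boundary knots (first-order Taylor expansion at the
boundary), which is the defining property of the natural spline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "BasisMatrix",
    "running_sum",
    "percentile_knots",
    "log_lag_knots",
    "ns_basis",
    "cross_basis",
    "month_indicators",
]


@dataclass(frozen=True)
class SplineSpec:
    """Natural cubic spline definition: internal knots, boundary pair, intercept flag."""

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    intercept: bool = False

    def __post_init__(self) -> None:
        ik = tuple(float(k) for k in self.internal_knots)
        bk = (float(self.boundary_knots[0]), float(self.boundary_knots[1]))
        object.__setattr__(self, "internal_knots", ik)
        object.__setattr__(self, "boundary_knots", bk)
        if not bk[0] < bk[1]:
            raise ValueError(f"boundary knots must be increasing, got {bk}")
        if any(not bk[0] < k < bk[1] for k in ik):
            raise ValueError(
                f"internal knots {ik} must lie strictly inside boundary knots {bk}"
            )
        if any(a >= b for a, b in zip(ik, ik[1:])):
            raise ValueError(f"internal knots must be strictly increasing, got {ik}")

    @property
    def dim(self) -> int:
        """Number of basis columns: n_internal + 1 (+1 with intercept)."""
        return len(self.internal_knots) + 1 + (1 if self.intercept else 0)

    def to_dict(self) -> dict:
        return {
            "internal_knots": list(self.internal_knots),
            "boundary_knots": list(self.boundary_knots),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            internal_knots=tuple(d["internal_knots"]),
            boundary_knots=tuple(d["boundary_knots"]),
            intercept=bool(d["intercept"]),
        )


@dataclass(frozen=True)
class CrossBasisSpec:
    """Exposure-lag cross-basis: a spline over temperature crossed with a spline over lag.

    ``var_spec`` carries the temperature knots (33rd/67th percentiles in the
    default model); ``lag_spec`` is a natural spline over lag 0..max_lag with
    an intercept and internal knots equally spaced on the log-lag scale.
    """

    var_spec: SplineSpec
    lag_spec: SplineSpec
    max_lag: int = 28

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        lo, hi = self.lag_spec.boundary_knots
        if not (lo == 0.0 and hi == float(self.max_lag)):
            raise ValueError(
                f"lag spline boundary knots must be (0, {self.max_lag}), got {(lo, hi)}"
            )
        if any(not 0.0 < k < self.max_lag for k in self.lag_spec.internal_knots):
            raise ValueError("lag knots must lie strictly inside (0, max_lag)")

    @property
    def dim(self) -> int:
        return self.var_spec.dim * self.lag_spec.dim

    def to_dict(self) -> dict:
        return {
            "var_spec": self.var_spec.to_dict(),
            "lag_spec": self.lag_spec.to_dict(),
            "max_lag": self.max_lag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossBasisSpec":
        return cls(
            var_spec=SplineSpec.from_dict(d["var_spec"]),
            lag_spec=SplineSpec.from_dict(d["lag_spec"]),
            max_lag=int(d["max_lag"]),
        )


@dataclass
class BasisMatrix:
    """Evaluated design columns plus the mask of days with complete history.

    Rows where ``usable_mask`` is False are NaN and must be excluded from
    fitting; they correspond to days without the full prior exposure window
    or lag history.
    """

    values: np.ndarray
    spec: object
    usable_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.usable_mask is None:
            self.usable_mask = np.ones(self.values.shape[0], dtype=bool)
        self.usable_mask = np.asarray(self.usable_mask, dtype=bool)

    @property
    def usable(self) -> np.ndarray:
        return self.values[self.usable_mask]


def running_sum(precip: np.ndarray, window: int) -> np.ndarray:
    """Sum of precipitation over the ``window`` days strictly preceding each day.

    Value at day t is ``sum(precip[t-window : t])``; the exposure window
    excludes the death day itself.  The first ``window`` days have no
    complete history and are returned as NaN.
    """
    precip = np.asarray(precip, dtype=float)
    n = precip.shape[0]
    if window < 1:
        raise ValueError("window must be >= 1")
    if window >= n:
        raise ValueError(f"window ({window}) must be shorter than the series ({n})")
    if np.isnan(precip).any():
        raise ValueError("precipitation series contains missing values")
    csum = np.concatenate([[0.0], np.cumsum(precip)])
    out = np.full(n, np.nan)
    # sum over [t-window, t-1] = csum[t] - csum[t-window]
    t = np.arange(window, n)
    out[t] = csum[t] - csum[t - window]
    return out


def percentile_knots(
    x: np.ndarray, percentiles: list[float], intercept: bool = False
) -> SplineSpec:
    """Spline spec with internal knots at empirical percentiles, boundary at min/max.

    Percentiles use the linear-interpolation definition.  Degenerate
    distributions (duplicate knot or boundary values) are rejected.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values to place knots on")
    knots = np.percentile(x, percentiles, method="linear")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo >= hi:
        raise ValueError("degenerate distribution: min equals max")
    vals = np.concatenate([[lo], knots, [hi]])
    if np.any(np.diff(vals) <= 0):
        raise ValueError(
            f"degenerate knot placement {vals.tolist()}: duplicate or non-increasing knots"
        )
    return SplineSpec(
        internal_knots=tuple(float(k) for k in knots),
        boundary_knots=(lo, hi),
        intercept=intercept,
    )


def log_lag_knots(max_lag: int = 28, n_knots: int = 3) -> np.ndarray:
    """Internal lag knots equally spaced on the log scale in (0, max_lag).

    For n knots the positions are ``max_lag ** (i / (n+1))`` for i = 1..n,
    i.e. exp of equally spaced points strictly between 0 and log(max_lag).
    """
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    if max_lag <= 1:
        raise ValueError("max_lag must be > 1")
    expo = np.arange(1, n_knots + 1) / (n_knots + 1)
    return np.asarray(max_lag, dtype=float) ** expo


def _ns_design(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Natural cubic spline basis evaluated pointwise at x (no mask logic)."""
    x = np.asarray(x, dtype=float)
    lo, hi = spec.boundary_knots
    t = np.concatenate(
        [[lo] * 4, np.asarray(spec.internal_knots, dtype=float), [hi] * 4]
    )
    m = len(spec.internal_knots) + 4  # cubic B-spline dimension
    bs = BSpline(t, np.eye(m), 3, extrapolate=False)
    d1 = bs.derivative(1)
    d2 = bs.derivative(2)

    xc = np.clip(x, lo, hi)
    B = bs(xc)
    # linear (first-order Taylor) extension beyond the boundary knots
    below = x < lo
    above = x > hi
    if below.any():
        B[below] = bs(lo) + np.outer(x[below] - lo, d1(lo))
    if above.any():
        B[above] = bs(hi) + np.outer(x[above] - hi, d1(hi))

    if not spec.intercept:
        B = B[:, 1:]
        const = np.vstack([d2(lo)[1:], d2(hi)[1:]])
    else:
        const = np.vstack([d2(lo), d2(hi)])
    # project onto the null space of the boundary second-derivative constraints
    q, _ = np.linalg.qr(const.T, mode="complete")
    return B @ q[:, 2:]


def ns_basis(x: np.ndarray, spec: SplineSpec) -> BasisMatrix:
    """Natural cubic spline basis: linear beyond the boundary knots, C2 inside.

    Column count follows the spec invariant (n_internal + 1, plus one with an
    intercept).  Evaluation is pointwise, so rows with NaN input yield NaN
    rows flagged unusable.
    """
    x = np.asarray(x, dtype=float)
    mask = np.isfinite(x)
    out = np.full((x.shape[0], spec.dim), np.nan)
    if mask.any():
        out[mask] = _ns_design(x[mask], spec)
    return BasisMatrix(values=out, spec=spec, usable_mask=mask)


def cross_basis(temp: np.ndarray, spec: CrossBasisSpec) -> BasisMatrix:
    """Temperature exposure-lag cross-basis.

    Column (j, k) at day t is ``sum_{l=0..L} v_j(temp[t-l]) * w_k(l)`` with
    v the temperature basis and w the lag basis (lag basis includes its
    intercept).  The first ``max_lag`` days lack a full lag history and are
    flagged unusable rather than imputed.
    """
    temp = np.asarray(temp, dtype=float)
    n = temp.shape[0]
    L = spec.max_lag
    if n <= L:
        raise ValueError(f"series length ({n}) must exceed max_lag ({L})")
    V = _ns_design(temp, spec.var_spec)  # (n, J)
    lags = np.arange(L + 1, dtype=float)
    W = _ns_design(lags, spec.lag_spec)  # (L+1, K)
    J, K = V.shape[1], W.shape[1]
    out = np.full((n, J * K), np.nan)
    # lagged stack of V: for usable t, rows t-0..t-L
    idx = np.arange(L, n)
    # shape (n_usable, L+1, J): V[t - l]
    lagged = V[idx[:, None] - np.arange(L + 1)[None, :]]
    # contract over lag with W -> (n_usable, J, K)
    xb = np.einsum("tlj,lk->tjk", lagged, W)
    out[idx] = xb.reshape(len(idx), J * K)
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return BasisMatrix(values=out, spec=spec, usable_mask=mask)


def month_indicators(dates) -> BasisMatrix:
    """Eleven dummy columns, one per calendar month Feb..Dec (January is reference)."""
    import pandas as pd

    months = pd.DatetimeIndex(dates).month.to_numpy()
    out = np.zeros((months.shape[0], 11))
    for j, m in enumerate(range(2, 13)):
        out[:, j] = months == m
    return BasisMatrix(values=out, spec="month_indicators")
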