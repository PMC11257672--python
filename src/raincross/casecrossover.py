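"""First-stage fitting: time-stratified case-crossover conditional quasi-Poisson.

Each location's daily death counts are regressed on the precipitation
spline, the temperature cross-basis and month indicators, conditioning on
time strata (year x quarterly months x day of week by default, so each
death day is compared against the ~12 other same-weekday days of its
quarter).  Conditioning is implemented by profiling out the stratum
intercepts exactly — for a Poisson likelihood the stratum intercept given
the slopes has the closed form ``alpha_c = log(sum_c y / sum_c exp(x'b))``
— which is equivalent to a Poisson fit with one dummy intercept per
stratum (the test oracle) but never materialises the dummies.

Overdispersion is handled quasi-likelihood style: the coefficient
covariance is the inverse Fisher information scaled by the Pearson
dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LocationSeries
from .splines import (
    CrossBasisSpec,
    SplineSpec,
    cross_basis,
    log_lag_knots,
    month_indicators,
    ns_basis,
    percentile_knots,
    running_sum,
)

__all__ = [
    "StratumScheme",
    "StageOneFit",
    "ConvergenceError",
    "assign_strata",
    "fit_conditional_quasipoisson",
    "fit_location",
]


class ConvergenceError(RuntimeError):
    """Raised when the IRLS loop fails to converge; carries the deviance trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message}; deviance trace: {trace}")
        self.trace = trace


@dataclass(frozen=True)
class StratumScheme:
    """Case-crossover stratification: quarter x weekday (default) or month x weekday.

    ``quarter_offset`` shifts the quarterly blocks: 0 = Jan-Mar, Apr-Jun, ...;
    1 = Feb-Apr, ...; 2 = Mar-May, ... (the Nov/Dec-Jan block spans the year
    boundary and takes its year from the block's first month).
    """

    kind: str = "quarter_dow"
    quarter_offset: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("quarter_dow", "month_dow"):
            raise ValueError(f"unknown stratum kind {self.kind!r}")
        if self.quarter_offset not in (0, 1, 2):
            raise ValueError("quarter_offset must be 0, 1 or 2")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "quarter_offset": self.quarter_offset}


def assign_strata(dates, scheme: StratumScheme) -> np.ndarray:
    """Stratum label per day: every day maps to exactly one stratum."""
    idx = pd.DatetimeIndex(dates)
    year = idx.year.to_numpy()
    month = idx.month.to_numpy()
    dow = idx.dayofweek.to_numpy()
    if scheme.kind == "month_dow":
        labels = [f"{y}-m{m:02d}-d{d}" for y, m, d in zip(year, month, dow)]
    else:
        k = scheme.quarter_offset
        shifted = (month - 1 - k) % 12
        block = shifted // 3
        block_year = np.where(month <= k, year - 1, year)
        labels = [
            f"{y}-q{b}-d{d}" for y, b, d in zip(block_year, block, dow)
        ]
    return np.asarray(labels)


def _unaliased_columns(M: np.ndarray, rtol: float = 1e-8) -> list[int]:
    """First-come maximal independent column subset (modified Gram-Schmidt)."""
    n, p = M.shape
    Q = np.empty((n, 0))
    kept: list[int] = []
    for j in range(p):
        c = M[:, j].astype(float)
        nrm0 = np.linalg.norm(c)
        if nrm0 == 0:
            continue
        r = c - Q @ (Q.T @ c)
        r = r - Q @ (Q.T @ r)  # reorthogonalize
        nrm = np.linalg.norm(r)
        if nrm > rtol * nrm0:
            Q = np.column_stack([Q, r / nrm])
            kept.append(j)
    return kept


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_conditional_quasipoisson(
    y: np.ndarray,
    X: np.ndarray,
    strata: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> dict:
    """Conditional quasi-Poisson fit with stratum intercepts profiled out.

    Returns a dict with ``coef``, ``vcov`` (dispersion-scaled), ``dispersion``
    (Pearson chi-square / residual df), ``n_strata_used``, ``deviance`` and
    the iteration trace.  Strata whose deaths total zero contribute nothing
    to the conditional likelihood and are dropped; columns without
    within-stratum variation are inestimable and rejected.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("y and X must have matching rows")
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values on fitted rows")
    if not (y >= 0).all():
        raise ValueError("counts must be non-negative")
    if y.sum() == 0:
        raise ValueError("all-zero outcome: conditional likelihood is degenerate")

    codes, _ = pd.factorize(strata, sort=True)
    totals = np.bincount(codes, weights=y)
    keep_stratum = totals > 0
    keep = keep_stratum[codes]
    y, X, codes = y[keep], X[keep], codes[keep]
    codes, _ = pd.factorize(codes, sort=True)  # recompact
    n_strata = int(codes.max()) + 1
    n, p = X.shape
    ytot = np.bincount(codes, weights=y, minlength=n_strata)

    # inestimable columns: no variation within any used stratum
    strat_mean = np.zeros((n_strata, p))
    cnt = np.bincount(codes, minlength=n_strata).astype(float)
    for j in range(p):
        strat_mean[:, j] = np.bincount(codes, weights=X[:, j], minlength=n_strata) / cnt
    within = X - strat_mean[codes]
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    dead = np.abs(within).max(axis=0) < 1e-10 * scale
    if dead.any():
        raise ValueError(
            f"columns {np.where(dead)[0].tolist()} are constant within every stratum "
            "(absorbed by stratum intercepts) and are inestimable"
        )
    # Columns collinear *after* stratum absorption are aliased and dropped,
    # mirroring how dummy-variable GLM software aliases them. (With quarterly
    # strata and month indicators this is structural: each quarter is a month
    # triple, so three month-dummy sums equal stratum indicators.)
    kept = _unaliased_columns(within)
    aliased = sorted(set(range(p)) - set(kept))
    if aliased:
        X = X[:, kept]
        p = len(kept)

    beta = np.zeros(p)
    trace: list[float] = []
    dev_old = np.inf
    XtWX = None
    for _ in range(max_iter):
        eta_x = X @ beta
        ex = np.exp(eta_x)
        extot = np.bincount(codes, weights=ex, minlength=n_strata)
        alpha = np.log(ytot / extot)
        mu = ex * np.exp(alpha[codes])
        dev = _poisson_deviance(y, mu)
        trace.append(dev)
        if np.isfinite(dev_old) and abs(dev - dev_old) <= tol * abs(dev_old) + 1e-12:
            break
        dev_old = dev
        w = mu
        z = (eta_x + alpha[codes]) + (y - mu) / mu
        # absorb stratum intercepts: weighted within-stratum centering
        wtot = np.bincount(codes, weights=w, minlength=n_strata)
        Xc = np.empty_like(X)
        for j in range(p):
            mj = np.bincount(codes, weights=w * X[:, j], minlength=n_strata) / wtot
            Xc[:, j] = X[:, j] - mj[codes]
        zm = np.bincount(codes, weights=w * z, minlength=n_strata) / wtot
        zc = z - zm[codes]
        XtWX = (Xc * w[:, None]).T @ Xc
        XtWz = (Xc * w[:, None]).T @ zc
        try:
            beta = np.linalg.solve(XtWX, XtWz)
        except np.linalg.LinAlgError as e:
            raise ValueError(f"singular information matrix: {e}") from e
    else:
        raise ConvergenceError("IRLS did not converge", trace)

    eta_x = X @ beta
    ex = np.exp(eta_x)
    extot = np.bincount(codes, weights=ex, minlength=n_strata)
    alpha = np.log(ytot / extot)
    mu = ex * np.exp(alpha[codes])
    pearson = float(np.sum((y - mu) ** 2 / mu))
    resid_df = n - p - n_strata
    if resid_df <= 0:
        import warnings

        warnings.warn(
            f"non-positive residual df ({resid_df}): dispersion indeterminate, using 1.0",
            stacklevel=2,
        )
        dispersion = 1.0
    else:
        dispersion = pearson / resid_df
    # information at convergence (recompute centered design at final weights)
    w = mu
    wtot = np.bincount(codes, weights=w, minlength=n_strata)
    Xc = np.empty_like(X)
    for j in range(p):
        mj = np.bincount(codes, weights=w * X[:, j], minlength=n_strata) / wtot
        Xc[:, j] = X[:, j] - mj[codes]
    XtWX = (Xc * w[:, None]).T @ Xc
    vcov = dispersion * np.linalg.inv(XtWX)
    return {
        "coef": beta,
        "vcov": vcov,
        "dispersion": dispersion,
        "n_strata_used": n_strata,
        "deviance": trace[-1],
        "trace": trace,
        "n_obs": n,
        "kept": kept,
        "aliased": aliased,
    }


@dataclass
class StageOneFit:
    """Per-location precipitation-basis coefficients, covariance and diagnostics."""

    location_id: str
    country: str
    climate: str
    beta: np.ndarray
    vcov_beta: np.ndarray
    dispersion: float
    n_strata_used: int
    spec: SplineSpec
    percentiles: dict[str, float]  # "min", "p1".."p99", "max" of 28-day sums (mm)
    n_days_used: int = 0
    meta_predictors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.vcov_beta = np.asarray(self.vcov_beta, dtype=float)
        k = self.beta.shape[0]
        if self.vcov_beta.shape != (k, k):
            raise ValueError("vcov_beta must be k x k")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not np.allclose(self.vcov_beta, self.vcov_beta.T, atol=1e-10):
            raise ValueError("vcov_beta must be symmetric")
        if np.linalg.eigvalsh((self.vcov_beta + self.vcov_beta.T) / 2).min() < -1e-8:
            raise ValueError("vcov_beta must be positive semidefinite")

    def to_dict(self) -> dict:
        return {
            "location_id": self.location_id,
            "country": self.country,
            "climate": self.climate,
            "beta": self.beta.tolist(),
            "vcov_beta": self.vcov_beta.tolist(),
            "dispersion": self.dispersion,
            "n_strata_used": self.n_strata_used,
            "spec": self.spec.to_dict(),
            "percentiles": self.percentiles,
            "n_days_used": self.n_days_used,
            "meta_predictors": self.meta_predictors,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageOneFit":
        return cls(
            location_id=d["location_id"],
            country=d["country"],
            climate=d["climate"],
            beta=np.asarray(d["beta"]),
            vcov_beta=np.asarray(d["vcov_beta"]),
            dispersion=d["dispersion"],
            n_strata_used=d["n_strata_used"],
            spec=SplineSpec.from_dict(d["spec"]),
            percentiles=d["percentiles"],
            n_days_used=d.get("n_days_used", 0),
            meta_predictors=d.get("meta_predictors", {}),
        )


def percentile_table(values: np.ndarray) -> dict[str, float]:
    """min, p1..p99, max of a sample — the per-location exposure distribution record."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    out = {"min": float(values.min()), "max": float(values.max())}
    qs = np.percentile(values, np.arange(1, 100))
    for i, q in enumerate(qs, start=1):
        out[f"p{i}"] = float(q)
    return out


def build_design(
    series: LocationSeries,
    window: int = 28,
    precip_spec: SplineSpec | None = None,
    precip_knot_percentiles: tuple[float, ...] = (50.0, 90.0),
    temp_knot_percentiles: tuple[float, ...] = (33.0, 67.0),
    max_lag: int = 28,
    n_lag_knots: int = 3,
    include_month_indicator: bool = True,
) -> dict:
    """Assemble the first-stage design for one location.

    Returns the stacked design, the usable-day mask, the precipitation
    block's column slice and the (possibly supplied) precipitation spline
    spec.  When ``precip_spec`` is None the knots are placed at the
    requested percentiles of this location's usable-day 28-day sums.
    """
    cum = running_sum(series.precip, window)
    if precip_spec is None:
        precip_spec = percentile_knots(cum, list(precip_knot_percentiles))
    pb = ns_basis(cum, precip_spec)

    temp = series.temp
    lag_usable = np.zeros(len(temp), dtype=bool)
    lag_usable[max_lag:] = True
    var_spec = percentile_knots(temp[lag_usable], list(temp_knot_percentiles))
    lag_spec = SplineSpec(
        internal_knots=tuple(log_lag_knots(max_lag, n_lag_knots)),
        boundary_knots=(0.0, float(max_lag)),
        intercept=True,
    )
    cb = cross_basis(temp, CrossBasisSpec(var_spec, lag_spec, max_lag=max_lag))

    blocks = [pb.values, cb.values]
    names = (
        [f"precip{i}" for i in range(precip_spec.dim)]
        + [f"crossbasis{i}" for i in range(cb.values.shape[1])]
    )
    if include_month_indicator:
        mi = month_indicators(series.dates)
        blocks.append(mi.values)
        names += [f"month{m}" for m in range(2, 13)]
    X = np.column_stack(blocks)
    usable = pb.usable_mask & cb.usable_mask
    return {
        "X": X,
        "usable": usable,
        "names": names,
        "precip_slice": slice(0, precip_spec.dim),
        "precip_spec": precip_spec,
        "cum": cum,
    }


def fit_location(
    series: LocationSeries,
    window: int = 28,
    scheme: StratumScheme | None = None,
    precip_spec: SplineSpec | None = None,
    precip_knot_percentiles: tuple[float, ...] = (50.0, 90.0),
    temp_knot_percentiles: tuple[float, ...] = (33.0, 67.0),
    max_lag: int = 28,
    n_lag_knots: int = 3,
    include_month_indicator: bool = True,
    meta_predictors: dict | None = None,
) -> StageOneFit:
    """Fit the case-crossover model for one location; return the precipitation block.

    The temperature cross-basis and month coefficients are nuisance terms:
    estimated, then discarded — only the precipitation-spline block and its
    covariance feed the second stage, together with the location's exposure
    percentile table.
    """
    scheme = scheme or StratumScheme()
    if scheme.kind == "month_dow":
        include_month_indicator = False  # month is absorbed by the strata
    d = build_design(
        series,
        window=window,
        precip_spec=precip_spec,
        precip_knot_percentiles=precip_knot_percentiles,
        temp_knot_percentiles=temp_knot_percentiles,
        max_lag=max_lag,
        n_lag_knots=n_lag_knots,
        include_month_indicator=include_month_indicator,
    )
    strata = assign_strata(series.dates, scheme)
    m = d["usable"]
    res = fit_conditional_quasipoisson(series.deaths[m], d["X"][m], strata[m])
    sl = d["precip_slice"]
    precip_idx = list(range(sl.start, sl.stop))
    if any(j not in res["kept"] for j in precip_idx):
        raise ValueError(
            f"precipitation basis columns aliased for {series.location_id}: "
            f"aliased={res['aliased']}"
        )
    pos = [res["kept"].index(j) for j in precip_idx]
    return StageOneFit(
        location_id=series.location_id,
        country=series.country,
        climate=series.climate,
        beta=res["coef"][pos],
        vcov_beta=res["vcov"][np.ix_(pos, pos)],
        dispersion=res["dispersion"],
        n_strata_used=res["n_strata_used"],
        spec=d["precip_spec"],
        percentiles=percentile_table(d["cum"][m]),
        n_days_used=res["n_obs"],
        meta_predictors=dict(meta_predictors or {}),
    )
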