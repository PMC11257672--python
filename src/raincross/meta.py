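"""Second stage: multivariate multilevel meta-regression of spline coefficients.

Location-level coefficient vectors ``beta_i`` (k precipitation-basis
coefficients each, with within-location covariance ``S_i`` from the first
stage) are pooled under the model

    beta_i = X_i gamma + g_{j(i)} + e_i,
    g_j ~ N(0, Psi),   e_i ~ N(0, S_i),

where ``X_i`` encodes climate-zone fixed effects (plus optional centered
continuous meta-predictors), and ``g_j`` is a country-level random
coefficient vector shared by all of country j's locations.  ``Psi`` is
estimated by restricted maximum likelihood over its Cholesky factor;
``gamma`` follows by generalized least squares at the REML ``Psi``.

Residual heterogeneity is summarised by Cochran's Q (computed at the
fixed-effect, ``Psi = 0`` solution) and I² = max(0, (Q - df)/Q) x 100; the
joint significance of a predictor block comes from a Wald chi-square; and
per-location coefficient vectors are shrunk via best linear unbiased
prediction (BLUP) of the country random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .casecrossover import StageOneFit
from .core import CLIMATES

__all__ = ["MetaFit", "pool", "cochran_q", "i_squared", "wald_predictor_test", "blup"]


@dataclass
class MetaFit:
    """Pooled fixed effects, between-country covariance and heterogeneity summaries."""

    gamma: np.ndarray
    vcov_gamma: np.ndarray
    psi: np.ndarray
    Q: float
    Q_df: int
    Q_p: float
    I2: float
    wald: dict  # {"statistic", "df", "p"} for the climate predictor (if present)
    blups: dict  # location_id -> {"coef": [...], "vcov": [...]}
    k: int
    climate_levels: tuple[str, ...]
    reference_level: str
    meta_predictor: str | None = None
    psi_structure: str = "unstructured"
    reml_loglik: float = float("nan")
    converged: bool = True
    details: dict = field(default_factory=dict)

    def climate_coef(self, climate: str) -> tuple[np.ndarray, np.ndarray]:
        """Pooled coefficient vector and covariance for one climate zone.

        The climate curve is intercept block + (contrast block if the climate
        is not the reference level); any continuous meta-predictor is held at
        its centered zero (i.e., the predictor's mean).
        """
        if climate not in self.climate_levels:
            raise KeyError(f"climate {climate!r} not in fit ({self.climate_levels})")
        k = self.k
        A = np.zeros((k, len(self.gamma)))
        A[:, :k] = np.eye(k)
        if climate != self.reference_level:
            pos = 1 + [c for c in self.climate_levels if c != self.reference_level].index(climate)
            A[:, pos * k : (pos + 1) * k] = np.eye(k)
        coef = A @ self.gamma
        vcov = A @ self.vcov_gamma @ A.T
        return coef, vcov

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma.tolist(),
            "vcov_gamma": self.vcov_gamma.tolist(),
            "psi": self.psi.tolist(),
            "Q": self.Q,
            "Q_df": self.Q_df,
            "Q_p": self.Q_p,
            "I2": self.I2,
            "wald": self.wald,
            "blups": self.blups,
            "k": self.k,
            "climate_levels": list(self.climate_levels),
            "reference_level": self.reference_level,
            "meta_predictor": self.meta_predictor,
            "psi_structure": self.psi_structure,
            "reml_loglik": self.reml_loglik,
            "converged": self.converged,
        }


def _design_rows(
    fits: list[StageOneFit], meta_predictor: str | None
) -> tuple[np.ndarray, tuple[str, ...], str, np.ndarray | None]:
    """Per-location scalar design rows [1, climate contrasts, centered predictor]."""
    levels = tuple(c for c in CLIMATES if any(f.climate == c for f in fits))
    ref = levels[0]
    contrasts = [c for c in levels if c != ref]
    rows = []
    pred = None
    if meta_predictor is not None:
        vals = []
        for f in fits:
            if meta_predictor not in f.meta_predictors:
                raise KeyError(
                    f"meta-predictor {meta_predictor!r} missing for {f.location_id}"
                )
            vals.append(float(f.meta_predictors[meta_predictor]))
        pred = np.asarray(vals) - np.mean(vals)
    for i, f in enumerate(fits):
        r = [1.0] + [1.0 if f.climate == c else 0.0 for c in contrasts]
        if pred is not None:
            r.append(pred[i])
        rows.append(r)
    return np.asarray(rows), levels, ref, pred


def _stack(fits: list[StageOneFit], meta_predictor: str | None):
    k = fits[0].beta.shape[0]
    for f in fits:
        if f.beta.shape[0] != k:
            raise ValueError("all first-stage coefficient vectors must share a dimension")
        ev = np.linalg.eigvalsh((f.vcov_beta + f.vcov_beta.T) / 2)
        if ev.min() <= 0 and ev.min() < -1e-10:
            raise ValueError(f"non-PSD first-stage covariance for {f.location_id}")
    rows, levels, ref, _ = _design_rows(fits, meta_predictor)
    X = np.vstack([np.kron(r, np.eye(k)) for r in rows])  # (N*k, p)
    y = np.concatenate([f.beta for f in fits])
    countries = [f.country for f in fits]
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(countries):
        groups.setdefault(c, []).append(i)
    return y, X, groups, k, levels, ref, rows


def _nll_reml(y, X, S_list, groups, k, psi):
    """-2 x REML log-likelihood (up to an additive constant)."""
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    yVy = 0.0
    per_country = []
    for idxs in groups.values():
        nj = len(idxs)
        rows = np.concatenate([np.arange(i * k, (i + 1) * k) for i in idxs])
        Vj = np.zeros((nj * k, nj * k))
        for a, i in enumerate(idxs):
            Vj[a * k : (a + 1) * k, a * k : (a + 1) * k] = S_list[i]
        Vj += np.tile(psi, (nj, nj))
        try:
            L = np.linalg.cholesky(Vj)
        except np.linalg.LinAlgError:
            return np.inf, None
        logdet += 2.0 * np.sum(np.log(np.diag(L)))
        Xj = X[rows]
        yj = y[rows]
        Li_X = solve_triangular(L, Xj, lower=True)
        Li_y = solve_triangular(L, yj, lower=True)
        XtVX += Li_X.T @ Li_X
        XtVy += Li_X.T @ Li_y
        yVy += Li_y @ Li_y
        per_country.append((idxs, rows, L))
    sign, ld2 = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf, None
    gamma = np.linalg.solve(XtVX, XtVy)
    resid_quad = yVy - XtVy @ gamma
    nll = logdet + ld2 + resid_quad
    return nll, {"gamma": gamma, "XtVX": XtVX, "per_country": per_country}


def _chol_to_psi(theta: np.ndarray, k: int, structure: str) -> np.ndarray:
    if structure == "diagonal":
        return np.diag(theta**2)
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = theta
    return L @ L.T


def _psi_to_theta(psi: np.ndarray, structure: str) -> np.ndarray:
    k = psi.shape[0]
    if structure == "diagonal":
        return np.sqrt(np.maximum(np.diag(psi), 0.0))
    w, V = np.linalg.eigh((psi + psi.T) / 2)
    psi_psd = (V * np.maximum(w, 0.0)) @ V.T
    try:
        L = np.linalg.cholesky(psi_psd + 1e-10 * np.eye(k))
    except np.linalg.LinAlgError:
        L = np.diag(np.sqrt(np.maximum(np.diag(psi_psd), 0.0)))
    return L[np.tril_indices(k)]


def _fit_reml(y, X, S_list, groups, k, structure: str):
    nll = lambda th: _nll_reml(y, X, S_list, groups, k, _chol_to_psi(th, k, structure))[0]
    nth = k if structure == "diagonal" else k * (k + 1) // 2

    # method-of-moments start: marginal coefficient scatter minus mean S
    N = len(S_list)
    B = y.reshape(N, k)
    mom = np.cov(B.T, ddof=1) if N > 1 else np.zeros((k, k))
    mom = np.atleast_2d(mom) - np.mean(S_list, axis=0)
    starts = [
        np.full(nth, 1e-4),
        _psi_to_theta(np.atleast_2d(mom), structure),
    ]
    best = None
    for s0 in starts:
        r = optimize.minimize(nll, s0, method="Nelder-Mead",
                              options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        r2 = optimize.minimize(nll, r.x, method="BFGS", options={"maxiter": 500})
        cand = r2 if r2.fun <= r.fun else r
        if best is None or cand.fun < best.fun:
            best = cand
    psi = _chol_to_psi(best.x, k, structure)
    val, aux = _nll_reml(y, X, S_list, groups, k, psi)
    return psi, val, aux, bool(np.isfinite(val))


def pool(
    fits: list[StageOneFit],
    meta_predictor: str | None = None,
    psi_structure: str = "unstructured",
) -> MetaFit:
    """Pool first-stage coefficient vectors across locations.

    Fixed effects: one k-vector block per climate level present (reference
    level + contrasts) plus, optionally, a centered continuous meta-predictor
    interacting with the whole coefficient block.  Between-country
    heterogeneity is an unstructured k x k covariance estimated by REML,
    falling back to a diagonal structure if the unstructured optimum is
    rank-deficient.
    """
    if len(fits) < 2:
        raise ValueError("pooling needs at least 2 locations")
    y, X, groups, k, levels, ref, rows = _stack(fits, meta_predictor)
    S_list = [f.vcov_beta for f in fits]

    psi, nllval, aux, ok = _fit_reml(y, X, S_list, groups, k, psi_structure)
    structure = psi_structure
    if psi_structure == "unstructured":
        ev = np.linalg.eigvalsh((psi + psi.T) / 2)
        if ev.min() < 1e-10 * max(ev.max(), 1e-12):
            # rank-deficient unstructured optimum: refit with diagonal Psi
            psi_d, nll_d, aux_d, ok_d = _fit_reml(y, X, S_list, groups, k, "diagonal")
            psi, nllval, aux, ok = psi_d, nll_d, aux_d, ok_d
            structure = "diagonal"
    if not ok or aux is None:
        raise RuntimeError("REML optimization failed to produce a finite objective")

    gamma = aux["gamma"]
    vcov_gamma = np.linalg.inv(aux["XtVX"])

    Q, Q_df, Q_p = cochran_q(fits, X=X, y=y, k=k)
    I2 = i_squared(Q, Q_df)

    fit = MetaFit(
        gamma=gamma,
        vcov_gamma=vcov_gamma,
        psi=psi,
        Q=Q,
        Q_df=Q_df,
        Q_p=Q_p,
        I2=I2,
        wald={},
        blups={},
        k=k,
        climate_levels=levels,
        reference_level=ref,
        meta_predictor=meta_predictor,
        psi_structure=structure,
        reml_loglik=-0.5 * float(nllval),
        converged=ok,
    )
    if len(levels) > 1:
        fit.wald = wald_predictor_test(fit, "climate")
    fit.blups = blup(fit, fits)
    return fit


def cochran_q(
    fits: list[StageOneFit] | None = None,
    metafit: MetaFit | None = None,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    k: int | None = None,
    meta_predictor: str | None = None,
) -> tuple[float, int, float]:
    """Cochran's Q at the fixed-effect (Psi = 0) GLS solution.

    Q = sum_i r_i' S_i^{-1} r_i with r the residuals from the Psi = 0 fit;
    df = N*k - p; p-value from the chi-square upper tail.
    """
    if X is None or y is None or k is None:
        if fits is None:
            raise ValueError("either fits or (X, y, k) must be supplied")
        mp = metafit.meta_predictor if metafit is not None else meta_predictor
        y, X, _groups, k, _lv, _ref, _rows = _stack(fits, mp)
    S_list = [f.vcov_beta for f in fits]
    N = len(S_list)
    p = X.shape[1]
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    Winv = []
    for i in range(N):
        Si = S_list[i]
        Wi = np.linalg.inv(Si)
        Winv.append(Wi)
        Xi = X[i * k : (i + 1) * k]
        yi = y[i * k : (i + 1) * k]
        XtWX += Xi.T @ Wi @ Xi
        XtWy += Xi.T @ Wi @ yi
    gamma_fe = np.linalg.solve(XtWX, XtWy)
    Q = 0.0
    for i in range(N):
        r = y[i * k : (i + 1) * k] - X[i * k : (i + 1) * k] @ gamma_fe
        Q += float(r @ Winv[i] @ r)
    df = N * k - p
    pval = float(stats.chi2.sf(Q, df)) if df >= 1 else float("nan")
    return float(Q), int(df), pval


def i_squared(Q: float, df: int) -> float:
    """I² heterogeneity percentage: max(0, (Q - df)/Q) x 100."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if Q <= 0.0:
        return 0.0
    return float(max(0.0, (Q - df) / Q) * 100.0)


def wald_predictor_test(metafit: MetaFit, block: str) -> dict:
    """Wald chi-square for a named predictor block of the fixed effects.

    For ``"climate"`` the block is every contrast of non-reference climates
    against the reference, across all k basis coefficients.
    """
    k = metafit.k
    n_contrasts = len(metafit.climate_levels) - 1
    if block == "climate":
        if n_contrasts == 0:
            raise ValueError("climate block absent: single climate level")
        idx = np.arange(k, k * (1 + n_contrasts))
    elif block == "meta_predictor" or block == metafit.meta_predictor:
        if metafit.meta_predictor is None:
            raise KeyError("no meta-predictor in this fit")
        idx = np.arange(k * (1 + n_contrasts), k * (2 + n_contrasts))
    else:
        raise KeyError(f"unknown predictor block {block!r}")
    g = metafit.gamma[idx]
    V = metafit.vcov_gamma[np.ix_(idx, idx)]
    try:
        W = float(g @ np.linalg.solve(V, g))
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular covariance for block {block!r}: {e}") from e
    df = len(idx)
    return {"statistic": W, "df": df, "p": float(stats.chi2.sf(W, df))}


def blup(metafit: MetaFit, fits: list[StageOneFit]) -> dict:
    """Best linear unbiased prediction of each location's coefficient vector.

    The country random effect is predicted as
    ``g_j = Psi Z' V_j^{-1} (y_j - X_j gamma)`` from all of country j's
    locations jointly, then added to each of that country's fixed-effect
    predictions.  The reported covariance combines fixed-effect uncertainty
    with the conditional variance of ``g_j`` (cross-terms ignored).
    """
    k = metafit.k
    psi = metafit.psi
    y, X, groups, k2, _lv, _ref, _rows = _stack(fits, metafit.meta_predictor)
    if k2 != k:
        raise ValueError("dimension mismatch between metafit and fits")
    S_list = [f.vcov_beta for f in fits]
    out: dict = {}
    for country, idxs in groups.items():
        nj = len(idxs)
        rows = np.concatenate([np.arange(i * k, (i + 1) * k) for i in idxs])
        Vj = np.zeros((nj * k, nj * k))
        for a, i in enumerate(idxs):
            Vj[a * k : (a + 1) * k, a * k : (a + 1) * k] = S_list[i]
        Vj += np.tile(psi, (nj, nj))
        Z = np.tile(np.eye(k), (nj, 1))  # (nj*k, k)
        resid = y[rows] - X[rows] @ metafit.gamma
        Vinv_r = np.linalg.solve(Vj, resid)
        g_j = psi @ (Z.T @ Vinv_r)
        PZt_Vinv = np.linalg.solve(Vj, Z @ psi).T  # (k, nj*k) = psi Z' Vj^-1
        cond_var = psi - PZt_Vinv @ (Z @ psi)
        for i in idxs:
            Xi = X[i * k : (i + 1) * k]
            coef = Xi @ metafit.gamma + g_j
            vc = Xi @ metafit.vcov_gamma @ Xi.T + cond_var
            out[fits[i].location_id] = {
                "coef": coef.tolist(),
                "vcov": ((vc + vc.T) / 2).tolist(),
                "country": country,
            }
    return out
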