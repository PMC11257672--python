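"""Second-stage pooling: REML meta-regression, heterogeneity, Wald, BLUP."""

import numpy as np
import pytest

from raincross.casecrossover import StageOneFit
from raincross.meta import (
    MetaFit,
    blup,
    cochran_q,
    i_squared,
    pool,
    wald_predictor_test,
)
from raincross.splines import SplineSpec

SPEC1 = SplineSpec((), (0.0, 1.0))


def make_fit(i, country, beta, vcov, climate="tropical", predictors=None):
    b = np.atleast_1d(np.asarray(beta, dtype=float))
    V = np.atleast_2d(np.asarray(vcov, dtype=float))
    if V.shape == (1, 1) and len(b) > 1:
        V = np.eye(len(b)) * V[0, 0]
    return StageOneFit(
        f"loc{i}", country, climate, b, V, 1.0, 10, SPEC1,
        {"min": 0.0, "max": 1.0}, meta_predictors=predictors or {},
    )


def _reference_multivariate_dataset():
    """12 countries x 2 locations, k=2, two climates; oracle-checked below."""
    rng = np.random.default_rng(7)
    k = 2
    countries = [f"c{i:02d}" for i in range(12) for _ in (0, 1)]
    N = len(countries)
    climates = ["tropical" if i % 2 == 0 else "arid" for i in range(N)]
    Psi_true = np.array([[0.09, 0.03], [0.03, 0.06]])
    gmap = {c: rng.multivariate_normal(np.zeros(k), Psi_true) for c in sorted(set(countries))}
    mu = {"tropical": np.array([0.3, 0.1]), "arid": np.array([-0.2, 0.4])}
    fits = []
    for i in range(N):
        A = rng.normal(0, 0.1, (k, k))
        S = A @ A.T + 0.01 * np.eye(k)
        b = mu[climates[i]] + gmap[countries[i]] + rng.multivariate_normal(np.zeros(k), S)
        fits.append(
            StageOneFit(f"l{i}", countries[i], climates[i], b, S, 1.0, 10, SPEC1,
                        {"min": 0.0, "max": 1.0})
        )
    return fits


class TestPool:
    def test_zero_heterogeneity_limit(self):
        fits = [
            make_fit(1, "c1", [0.5], [[0.04]]),
            make_fit(2, "c2", [0.5], [[0.04]]),
        ]
        mf = pool(fits)
        assert mf.psi[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert mf.gamma[0] == pytest.approx(0.5, abs=1e-10)

    def test_fixed_effect_limit_equal_variances(self):
        # with Psi = 0 and equal variances v the GLS solution is the plain
        # mean with variance v/K
        from raincross.meta import _nll_reml, _stack

        v = 0.09
        vals = [0.2, 0.4, 0.9, 0.1]
        fits = [make_fit(i, f"c{i}", [vals[i]], [[v]]) for i in range(4)]
        y, X, groups, k, _lv, _ref, _rows = _stack(fits, None)
        _nll, aux = _nll_reml(y, X, [f.vcov_beta for f in fits], groups, k, np.zeros((1, 1)))
        assert aux["gamma"][0] == pytest.approx(np.mean(vals), abs=1e-12)
        assert np.linalg.inv(aux["XtVX"])[0, 0] == pytest.approx(v / 4, abs=1e-12)

    def test_matches_rma_mv_oracle(self):
        # frozen from metafor::rma.mv(y, V, mods=~outcome:climate-1,
        # random=~outcome|country, struct="UN", REML) on the same dataset
        fits = _reference_multivariate_dataset()
        mf = pool(fits)
        trop = mf.gamma[:2]
        arid_coef, arid_vcov = mf.climate_coef("arid")
        assert trop == pytest.approx([0.4586966, 0.1470705], abs=2e-5)
        assert arid_coef == pytest.approx([-0.0453492, 0.4557435], abs=2e-5)
        assert np.diag(mf.psi) == pytest.approx([0.0841489, 0.0148979], abs=2e-4)
        rho = mf.psi[0, 1] / np.sqrt(mf.psi[0, 0] * mf.psi[1, 1])
        assert rho == pytest.approx(0.7663099, abs=1e-3)
        se_trop = np.sqrt(np.diag(mf.vcov_gamma[:2, :2]))
        assert se_trop == pytest.approx([0.0921111, 0.0582163], abs=2e-5)
        assert np.sqrt(np.diag(arid_vcov)) == pytest.approx([0.0943361, 0.0524605], abs=2e-5)

    def test_meta_predictor_adds_block(self):
        rng = np.random.default_rng(0)
        fits = [
            make_fit(i, f"c{i % 4}", rng.normal(0, 0.3, 2), np.eye(2) * 0.05,
                     climate="tropical", predictors={"gdp": float(i)})
            for i in range(8)
        ]
        mf0 = pool(fits)
        mf1 = pool(fits, meta_predictor="gdp")
        assert len(mf1.gamma) - len(mf0.gamma) == 2
        w = wald_predictor_test(mf1, "meta_predictor")
        assert w["df"] == 2 and 0 <= w["p"] <= 1

    def test_fewer_than_two_locations_rejected(self):
        with pytest.raises(ValueError):
            pool([make_fit(1, "c1", [0.1], [[0.01]])])


class TestCochranQ:
    def test_two_study_closed_form(self):
        y1, y2, v1, v2 = 0.3, 0.8, 0.02, 0.05
        fits = [make_fit(1, "c1", [y1], [[v1]]), make_fit(2, "c2", [y2], [[v2]])]
        Q, df, p = cochran_q(fits)
        assert Q == pytest.approx((y1 - y2) ** 2 / (v1 + v2), abs=1e-10)
        assert df == 1

    def test_identical_estimates_give_zero_q(self):
        fits = [make_fit(i, f"c{i}", [0.4], [[0.03]]) for i in range(4)]
        Q, df, p = cochran_q(fits)
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_to_location_order(self, rng):
        fits = [
            make_fit(i, f"c{i % 3}", rng.normal(0, 0.5, 2), np.eye(2) * rng.uniform(0.01, 0.1))
            for i in range(7)
        ]
        Q1, df1, _ = cochran_q(fits)
        Q2, df2, _ = cochran_q(fits[::-1])
        assert Q1 == pytest.approx(Q2, rel=1e-12)
        assert df1 == df2


class TestISquared:
    @pytest.mark.parametrize(
        "Q,df,expected", [(0.0, 5, 0.0), (5.0, 5, 0.0), (10.0, 5, 50.0), (20.0, 5, 75.0)]
    )
    def test_closed_form(self, Q, df, expected):
        assert i_squared(Q, df) == pytest.approx(expected, abs=1e-10)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            i_squared(1.0, 0)


class TestWald:
    def _toy_metafit(self, gamma, vcov, k=1, levels=("tropical", "arid")):
        return MetaFit(
            gamma=np.asarray(gamma, dtype=float),
            vcov_gamma=np.asarray(vcov, dtype=float),
            psi=np.zeros((k, k)),
            Q=0.0, Q_df=1, Q_p=1.0, I2=0.0, wald={}, blups={},
            k=k, climate_levels=levels, reference_level=levels[0],
        )

    def test_zero_block_gives_zero_statistic(self):
        mf = self._toy_metafit([0.5, 0.0], np.eye(2) * 0.04)
        w = wald_predictor_test(mf, "climate")
        assert w["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert w["p"] == pytest.approx(1.0)

    def test_scalar_block_is_z_squared(self):
        g, se = 0.37, 0.12
        mf = self._toy_metafit([0.1, g], [[0.04, 0.0], [0.0, se**2]])
        w = wald_predictor_test(mf, "climate")
        assert w["statistic"] == pytest.approx((g / se) ** 2, abs=1e-10)

    def test_unknown_block_rejected(self):
        mf = self._toy_metafit([0.1, 0.2], np.eye(2))
        with pytest.raises(KeyError):
            wald_predictor_test(mf, "altitude")


class TestBlup:
    def _metafit(self, gamma, psi, k=1):
        return MetaFit(
            gamma=np.asarray(gamma, dtype=float),
            vcov_gamma=np.eye(len(np.atleast_1d(gamma))) * 1e-6,
            psi=np.atleast_2d(np.asarray(psi, dtype=float)),
            Q=0.0, Q_df=1, Q_p=1.0, I2=0.0, wald={}, blups={},
            k=k, climate_levels=("tropical",), reference_level="tropical",
        )

    def test_zero_psi_returns_fixed_prediction(self):
        mf = self._metafit([0.25], [[0.0]])
        fits = [make_fit(i, f"c{i}", [0.1 * i], [[0.05]]) for i in range(3)]
        b = blup(mf, fits)
        for rec in b.values():
            assert rec["coef"][0] == pytest.approx(0.25, abs=1e-12)

    def test_scalar_shrinkage_weight(self):
        psi, s, mu, y = 0.04, 0.01, 0.2, 0.6
        mf = self._metafit([mu], [[psi]])
        fits = [make_fit(1, "cA", [y], [[s]]), make_fit(2, "cB", [mu], [[s]])]
        b = blup(mf, fits)
        w = psi / (psi + s)
        assert b["loc1"]["coef"][0] == pytest.approx(mu + w * (y - mu), abs=1e-10)

    def test_tiny_measurement_error_recovers_own_estimate(self):
        mf = self._metafit([0.0], [[0.05]])
        fits = [make_fit(1, "cA", [0.4], [[1e-10]])]
        b = blup(mf, fits)
        assert b["loc1"]["coef"][0] == pytest.approx(0.4, abs=1e-5)

    def test_blup_between_estimate_and_fixed_prediction(self, rng):
        mf = self._metafit([0.1], [[0.03]])
        for _ in range(10):
            y = float(rng.normal(0, 0.5))
            s = float(rng.uniform(0.005, 0.2))
            b = blup(mf, [make_fit(1, "cA", [y], [[s]])])["loc1"]["coef"][0]
            lo, hi = sorted([y, 0.1])
            assert lo - 1e-9 <= b <= hi + 1e-9


class TestShrinkagePooledStudy:
    def test_blups_shrink_toward_climate_means(self):
        # one location per country: the BLUP map is a contraction toward the
        # fixed prediction in the (Psi + S)^-1 metric. (With several locations
        # per country the sibling locations also inform the country effect and
        # a single location's BLUP may move past its own estimate.)
        base = _reference_multivariate_dataset()
        fits = [f for i, f in enumerate(base) if i % 2 == 0]  # first loc of each country
        mf = pool(fits)
        for f in fits:
            rec = mf.blups[f.location_id]
            pred, _ = mf.climate_coef(f.climate)
            W = np.linalg.inv(mf.psi + f.vcov_beta)
            d_blup = rec["coef"] - pred
            d_est = f.beta - pred
            assert d_blup @ W @ d_blup <= d_est @ W @ d_est + 1e-8
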