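"""Conditional quasi-Poisson fitting, dispersion and RR conversion."""

import numpy as np
import pytest

from casecrossover import (
    CollinearityError,
    FitResult,
    dispersion_estimate,
    fit,
    rr_from_fit,
)
from casecrossover.model import Z_975

from .conftest import per_replicate_seeds


def _random_instance(seed, n_strata=None, n_cov=None):
    rng = np.random.default_rng(seed)
    S = n_strata or rng.integers(2, 6)
    p = n_cov or rng.integers(1, 4)
    n = int(S * rng.integers(8, 20))
    codes = rng.integers(0, S, n)
    X = rng.normal(size=(n, p))
    alpha = rng.normal(1.0, 0.5, S)
    beta = rng.normal(0, 0.3, p)
    y = rng.poisson(np.exp(alpha[codes] + X @ beta))
    return y, X, codes


class TestFit:
    def test_single_stratum_binary_covariate_closed_form(self):
        # saturated two-group Poisson: beta = log(mean(y|x=1)/mean(y|x=0))
        y = np.array([1, 2, 3, 6])
        x = np.array([0.0, 0.0, 1.0, 1.0])[:, None]
        res = fit(y, x, np.zeros(4, dtype=int))
        assert res.beta[0] == pytest.approx(np.log(3), abs=1e-10)

    def test_no_signal_gives_zero_coefficient(self):
        # identical counts across covariate levels within every stratum
        y = np.array([4, 4, 4, 4, 7, 7, 7, 7])
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0])[:, None]
        codes = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = fit(y, x, codes)
        assert abs(res.beta[0]) < 1e-12

    def test_matches_stratum_dummy_glm_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        for seed in per_replicate_seeds(7, 10):
            y, X, codes = _random_instance(seed)
            res = fit(y, X, codes)
            D = np.eye(codes.max() + 1)[codes]
            oracle = sm.GLM(y, np.column_stack([X, D]), family=sm.families.Poisson()).fit()
            p = X.shape[1]
            np.testing.assert_allclose(res.beta, oracle.params[:p], rtol=1e-6, atol=1e-9)
            quasi = sm.GLM(
                y, np.column_stack([X, D]), family=sm.families.Poisson()
            ).fit(scale="X2")
            np.testing.assert_allclose(res.se(), quasi.bse[:p], rtol=1e-5, atol=1e-9)

    def test_translation_invariance_of_exposure(self):
        y, X, codes = _random_instance(11)
        res1 = fit(y, X, codes)
        res2 = fit(y, X + 123.4, codes)
        np.testing.assert_allclose(res1.beta, res2.beta, rtol=1e-7, atol=1e-10)

    def test_zero_total_strata_do_not_affect_coefficients(self):
        y, X, codes = _random_instance(13, n_strata=4)
        # append an all-zero stratum
        y2 = np.concatenate([y, np.zeros(10, dtype=int)])
        X2 = np.vstack([X, np.random.default_rng(0).normal(size=(10, X.shape[1]))])
        codes2 = np.concatenate([codes, np.full(10, 4)])
        res = fit(y, X, codes)
        res_with = fit(y2, X2, codes2)
        np.testing.assert_allclose(res.beta, res_with.beta, rtol=1e-10)
        assert res_with.n_strata == res.n_strata  # zero stratum not counted

    def test_duplicated_column_raises_collinearity_error(self):
        y, X, codes = _random_instance(17, n_cov=2)
        X2 = np.column_stack([X, X[:, 0]])
        with pytest.raises(CollinearityError):
            fit(y, X2, codes, column_names=["a", "b", "a_copy"])

    def test_stratum_constant_column_absorbed(self):
        y, X, codes = _random_instance(19, n_cov=1)
        X2 = np.column_stack([X, (codes == 0).astype(float)])
        with pytest.raises(CollinearityError, match="absorbed"):
            fit(y, X2, codes)
        res = fit(y, X2, codes, drop_absorbed=True)
        assert res.absorbed_columns == (1,)
        base = fit(y, X, codes)
        np.testing.assert_allclose(res.beta[0], base.beta[0], rtol=1e-10)

    def test_covariance_is_symmetric_psd(self):
        y, X, codes = _random_instance(23, n_cov=3)
        res = fit(y, X, codes)
        np.testing.assert_allclose(res.cov, res.cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(res.cov).min() >= -1e-12

    def test_nan_inputs_rejected(self):
        y, X, codes = _random_instance(29)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            fit(y, X, codes)


class TestDispersion:
    def test_zero_residuals_give_zero(self):
        mu = np.array([2.0, 3.0, 4.0])
        assert dispersion_estimate(mu, mu, 1) == 0.0

    def test_formula_small_example(self):
        y = np.array([1.0, 4.0])
        mu = np.array([2.0, 2.0])
        # sum((y-mu)^2/mu) = (1/2 + 4/2) = 2.5; df = 2 - 1
        assert dispersion_estimate(y, mu, 1) == pytest.approx(2.5)

    def test_no_residual_dof_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            dispersion_estimate(np.ones(3), np.ones(3), 3)

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            dispersion_estimate(np.ones(3), np.array([1.0, 0.0, 1.0]), 1)


class TestRREstimates:
    def _fit_result(self, beta, se):
        p = len(beta)
        return FitResult(
            beta=np.array(beta),
            cov=np.diag(np.array(se) ** 2),
            dispersion=1.0,
            n_obs=100,
            n_strata=10,
            converged=True,
            iterations=3,
            deviance=1.0,
            column_meta={i: i for i in range(p)},
        )

    def test_zero_coefficient_gives_rr_one(self):
        res = self._fit_result([0.0], [0.01])
        rr = rr_from_fit(res, 0, 10.0)
        assert rr.rr == 1.0
        assert rr.lo < 1.0 < rr.hi

    def test_inverse_construction(self):
        res = self._fit_result([np.log(1.08) / 10], [0.001])
        assert rr_from_fit(res, 0, 10.0).rr == pytest.approx(1.08, rel=1e-12)

    def test_ci_formula_direct_evaluation(self):
        res = self._fit_result([0.002], [0.001])
        rr = rr_from_fit(res, 0, 10.0)
        assert rr.lo == pytest.approx(np.exp(0.02 - Z_975 * 0.01), rel=1e-12)
        assert rr.hi == pytest.approx(np.exp(0.02 + Z_975 * 0.01), rel=1e-12)

    def test_missing_lag_is_lookup_error(self):
        res = self._fit_result([0.1], [0.01])
        with pytest.raises(KeyError):
            rr_from_fit(res, 5, 10.0)

    def test_dispersion_scaling_widens_ci_only(self):
        res = self._fit_result([0.002], [0.001])
        inflated = FitResult(
            beta=res.beta,
            cov=res.cov * 4.0,
            dispersion=4.0,
            n_obs=res.n_obs,
            n_strata=res.n_strata,
            converged=True,
            iterations=3,
            deviance=1.0,
            column_meta=res.column_meta,
        )
        rr0, rr1 = rr_from_fit(res, 0), rr_from_fit(inflated, 0)
        assert rr1.rr == rr0.rr
        assert (rr1.hi - rr1.lo) > (rr0.hi - rr0.lo)
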