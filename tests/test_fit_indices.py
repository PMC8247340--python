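"""Saturated/baseline likelihoods, fit indices, nested-model tests."""

import numpy as np
import pandas as pd
import pytest

import lgcmkit as lk
from lgcmkit.estimate import FitOptions, build_model_data, fit_model
from lgcmkit.fit_indices import (_obs_loglik, baseline_loglik, chi2_diff_pvalue,
                                 em_mvn, fit_statistics, lrt_compare,
                                 saturated_loglik)
from lgcmkit.model_spec import base_spec
from tests.conftest import apathy_only_config, m1_wide, warm_start


class TestEMSaturated:
    def test_complete_data_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        mu, sigma, ll = em_mvn(X)
        assert np.allclose(mu, X.mean(axis=0))
        assert np.allclose(sigma, np.cov(X.T, bias=True))
        assert ll == pytest.approx(_obs_loglik(X, mu, sigma))

    def test_matches_brute_force_on_missing_data(self):
        # direct numerical maximization over all 9 moment parameters
        from scipy.optimize import minimize

        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3)) @ np.array(
            [[1.0, 0.5, 0.2], [0, 1.0, 0.3], [0, 0, 1.0]])
        mask = rng.random((20, 3)) < 0.3
        mask[:, 0] &= ~(mask[:, 1] & mask[:, 2])  # keep every row observed
        Xm = X.copy()
        Xm[mask] = np.nan
        mu, sigma, ll = em_mvn(Xm, tol=1e-13, max_iter=5000)

        tril = np.tril_indices(3)

        def negll(v):
            L = np.zeros((3, 3))
            L[tril] = v[3:]
            try:
                return -_obs_loglik(Xm, v[:3], L @ L.T)
            except Exception:
                return 1e10

        v0 = np.concatenate([mu, np.linalg.cholesky(sigma)[tril]])
        res = minimize(negll, v0 * 1.05, method="Nelder-Mead",
                       options={"maxiter": 40000, "maxfev": 40000,
                                "fatol": 1e-13, "xatol": 1e-11})
        assert ll == pytest.approx(-res.fun, abs=1e-4)

    def test_likelihood_nondecreasing_via_internal_trap(self):
        # em_mvn raises if the likelihood ever decreases; a clean run on a
        # heavily missing matrix certifies monotone ascent
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 4))
        X[rng.random((60, 4)) < 0.35] = np.nan
        X[:, 0] = rng.normal(size=60)  # keep rows non-empty
        mu, sigma, ll = em_mvn(X)
        assert np.isfinite(ll)
        assert np.all(np.linalg.eigvalsh(sigma) > 0)


class TestBaseline:
    def _data(self, rho):
        rng = np.random.default_rng(5)
        cov = np.array([[1.0, rho, 0], [rho, 1.0, 0], [0, 0, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=400)
        spec = base_spec("s", ["y"], ["g"], [])
        wide = pd.DataFrame(X, columns=["y_t0", "y_t1", "y_t2"])
        wide["group"] = "g"
        return build_model_data(spec, wide)

    def test_complete_data_equals_univariate_mles(self):
        data = self._data(0.0)
        ll, k = baseline_loglik(data)
        X = np.vstack([p.rows for p in data.groups["g"].patterns])
        expected = sum(
            -0.5 * len(v) * (np.log(2 * np.pi) + np.log(v.var()) + 1.0)
            for v in X.T)
        assert ll == pytest.approx(expected, rel=1e-12)
        assert k == 6

    def test_diagonal_truth_makes_baseline_near_saturated(self):
        # twice the gap is ~ chi2(3) under a diagonal truth; bound at its
        # 99.9th percentile (the gap does not grow with n)
        from scipy.stats import chi2

        data = self._data(0.0)
        gap = saturated_loglik(data) - baseline_loglik(data)[0]
        assert 0 <= 2 * gap < chi2.ppf(0.999, 3)

    def test_strong_covariance_separates_baseline_from_saturated(self):
        weak = self._data(0.0)
        strong = self._data(0.8)
        gap_weak = saturated_loglik(weak) - baseline_loglik(weak)[0]
        gap_strong = saturated_loglik(strong) - baseline_loglik(strong)[0]
        assert gap_strong > gap_weak + 50


class TestFitStatistics:
    def test_well_specified_model_fits_well(self, small_fit):
        idx = fit_statistics(small_fit["fit"], small_fit["data"])
        assert idx.df == 11
        assert idx.chisq_per_df < 3
        assert idx.cfi > 0.95
        assert idx.srmr < 0.10
        assert idx.aic == pytest.approx(
            -2 * small_fit["fit"].loglik + 2 * small_fit["fit"].n_free)

    def test_rmsea_zero_and_cfi_one_when_chisq_below_df(self):
        # seed chosen so the well-specified model lands at chisq <= df
        for seed in range(30, 60):
            cfg = apathy_only_config(seed=seed, n_car=200, n_non=200)
            wide = m1_wide(cfg)
            spec = lk.behavioral_model(1)
            data = build_model_data(spec, wide)
            fit = fit_model(spec, data, FitOptions(compute_se=False))
            idx = fit_statistics(fit, data)
            if idx.chisq <= idx.df:
                assert idx.rmsea == 0.0
                assert idx.cfi == 1.0
                assert idx.rmsea_ci[0] == 0.0
                return
        pytest.fail("no replicate produced chisq <= df (expected ~55% each)")

    def test_rmsea_ci_brackets_point_estimate(self, small_fit):
        idx = fit_statistics(small_fit["fit"], small_fit["data"])
        lo, hi = idx.rmsea_ci
        assert lo <= max(idx.rmsea, lo) <= hi


class TestLRT:
    def test_printed_tail_probabilities(self):
        assert chi2_diff_pvalue(10.14, 1) == pytest.approx(0.0015, abs=5e-5)
        assert chi2_diff_pvalue(5.056, 1) == pytest.approx(0.025, abs=5e-4)
        assert chi2_diff_pvalue(7.206, 1) == pytest.approx(0.007, abs=5e-4)

    def test_identical_models_give_zero_and_p_one(self, small_fit):
        cmp = lrt_compare(small_fit["fit"], small_fit["fit"])
        assert cmp.delta_chisq == 0.0
        assert cmp.pvalue == 1.0

    def test_nested_comparison_consistency(self, small_fit):
        spec, data, fit = small_fit["spec"], small_fit["data"], small_fit["fit"]
        twin = lk.equate_slopes(spec)
        tfit = fit_model(twin, data, FitOptions(compute_se=False,
                                                start=warm_start(twin, fit)))
        cmp = lrt_compare(fit, tfit)
        assert cmp.delta_df == 1
        assert cmp.delta_chisq >= 0
        # Delta chisq equals the difference of model chi-squares
        i_free = fit_statistics(fit, data)
        i_con = fit_statistics(tfit, data)
        assert cmp.delta_chisq == pytest.approx(
            i_con.chisq - i_free.chisq, abs=1e-5)

    def test_non_nested_rejected(self, small_fit):
        other = lk.behavioral_model(3)
        with pytest.raises(ValueError):
            lrt_compare(small_fit["fit"],
                        lk.FitResult(spec=other, labels=[], theta=np.zeros(1),
                                     params=None, loglik=0.0, converged=True,
                                     n_iter=0, grad_norm=0, n_per_group={},
                                     n_free=other.n_free))
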