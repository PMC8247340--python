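"""FIML engine: implied moments, likelihood, fitting, robust SEs,
standardization — each checked against an independent route."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

import lgcmkit as lk
from lgcmkit.estimate import (FitOptions, ParamIndex, build_model_data,
                              casewise_loglik, fiml_loglik, fit_model)
from lgcmkit.model_spec import base_spec
from tests.conftest import apathy_only_config, m1_wide, warm_start


def _random_feasible_theta(spec, rng, psi_offdiag_scale=0.1):
    idx = ParamIndex(spec)
    th = psi_offdiag_scale * rng.standard_normal(idx.n_free)
    lb = np.array([b[0] for b in idx.bounds])
    th = np.where(lb == 0, np.abs(th) + 1.0, th)
    return idx, th


class TestImpliedMoments:
    def test_degenerate_closed_form(self):
        # Psi=0, Gamma=0: mean is the linear trajectory, covariance sigma^2 I
        spec = base_spec("s", ["y"], ["g"], [])
        gp = lk.GroupParams(
            alpha=np.array([1.0, 0.5]), psi=np.zeros((2, 2)),
            gamma=np.zeros((2, 0)), theta=np.array([0.3]),
            mu_x=np.zeros(0), phi_x=np.zeros((0, 0)))
        mu, sigma = lk.implied_moments(spec, gp)
        assert np.allclose(mu, [1.0, 1.5, 2.0])
        assert np.allclose(sigma, 0.3 * np.eye(3))

    def test_monte_carlo_moments_match(self):
        # empirical moments of a large simulated cohort match implied moments
        cfg = apathy_only_config(seed=8, dropout=0.0, n_car=50000, n_non=2)
        coh = lk.generate_cohort(cfg)
        wide = lk.analysis_table(coh, ["apathy"], predictors=("EYO",))
        car = wide[wide.group == "carrier"]
        cols = ["apathy_t0", "apathy_t1", "apathy_t2", "EYO"]
        emp_mu = car[cols].mean().to_numpy()
        emp_cov = car[cols].cov().to_numpy()

        spec = lk.behavioral_model(1)
        ap = cfg.outcomes["apathy"]
        gp = lk.GroupParams(
            alpha=np.array([ap.intercept_mean["carrier"], ap.slope_mean["carrier"]]),
            psi=np.asarray(ap.latent_cov["carrier"], dtype=float),
            gamma=np.array(ap.eyo_path["carrier"], dtype=float).reshape(2, 1),
            theta=np.array([ap.residual_var]),
            mu_x=np.array([cfg.eyo_mean["carrier"]]),
            phi_x=np.array([[cfg.eyo_sd["carrier"] ** 2]]))
        mu, sigma = lk.implied_moments(spec, gp)
        n = len(car)
        # sampling tolerance: ~4 SEs of a mean / covariance entry
        mu_tol = 4 * np.sqrt(np.diag(sigma) / n)
        assert np.all(np.abs(emp_mu - mu) < mu_tol)
        cov_tol = 4 * np.sqrt((np.outer(np.diag(sigma), np.diag(sigma))
                               + sigma ** 2) / n)
        assert np.all(np.abs(emp_cov - sigma) < cov_tol)


class TestFimlLoglik:
    def test_complete_data_equals_mvn(self):
        rng = np.random.default_rng(7)
        spec = lk.build_univariate("y", zero_noncarrier_slope=False)
        wide = pd.DataFrame(rng.normal(size=(40, 4)),
                            columns=["y_t0", "y_t1", "y_t2", "EYO"])
        wide["group"] = ["carrier"] * 20 + ["noncarrier"] * 20
        data = build_model_data(spec, wide)
        idx, th = _random_feasible_theta(spec, rng)
        ps = idx.unpack(th)
        ll = fiml_loglik(data, spec, ps)
        ll_mvn = sum(
            multivariate_normal.logpdf(
                np.vstack([p.rows for p in gd.patterns]),
                *lk.implied_moments(spec, ps[g])).sum()
            for g, gd in data.groups.items())
        assert ll == pytest.approx(ll_mvn, rel=1e-12)

    def test_single_univariate_observation_closed_form(self):
        spec = base_spec("s", ["y"], ["g"], [], n_waves=3)
        # collapse to: observe only y_t0 for each subject
        wide = pd.DataFrame({"y_t0": [1.7, 0.4], "y_t1": [np.nan] * 2,
                             "y_t2": [np.nan] * 2, "group": "g"})
        data = build_model_data(spec, wide)
        idx = ParamIndex(spec)
        gp = idx.unpack(idx.pack(lk.ParameterSet(groups={"g": lk.GroupParams(
            alpha=np.array([0.5, 0.0]), psi=np.diag([1.5, 0.0]),
            gamma=np.zeros((2, 0)), theta=np.array([0.5]),
            mu_x=np.zeros(0), phi_x=np.zeros((0, 0)))})))
        ll = fiml_loglik(data, spec, gp)
        mu, s2 = 0.5, 2.0  # intercept variance + residual
        expected = sum(-0.5 * (np.log(2 * np.pi) + np.log(s2) + (y - mu) ** 2 / s2)
                       for y in (1.7, 0.4))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_missing_wave_equals_explicit_marginal(self):
        rng = np.random.default_rng(3)
        spec = base_spec("s", ["y"], ["g"], [])
        wide = pd.DataFrame({"y_t0": [0.3, -0.2], "y_t1": [np.nan, 0.8],
                             "y_t2": [1.1, 0.9], "group": "g"})
        data = build_model_data(spec, wide)
        idx, th = _random_feasible_theta(spec, rng)
        ps = idx.unpack(th)
        ll = fiml_loglik(data, spec, ps)
        mu, sigma = lk.implied_moments(spec, ps["g"])
        keep = [0, 2]
        expected = multivariate_normal.logpdf(
            [0.3, 1.1], mu[keep], sigma[np.ix_(keep, keep)])
        expected += multivariate_normal.logpdf([-0.2, 0.8, 0.9], mu, sigma)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_infeasible_parameters_return_minus_inf(self):
        spec = base_spec("s", ["y"], ["g"], [])
        wide = pd.DataFrame({"y_t0": [0.0, 1], "y_t1": [0, 1], "y_t2": [0, 1.0],
                             "group": "g"})
        data = build_model_data(spec, wide)
        idx = ParamIndex(spec)
        th = np.zeros(idx.n_free)  # all variances 0 -> singular implied cov
        assert fiml_loglik(data, spec, idx.unpack(th)) == -np.inf

    def test_casewise_sums_to_total(self):
        rng = np.random.default_rng(11)
        spec = base_spec("s", ["y"], ["g"], [])
        Y = rng.normal(size=(25, 3))
        Y[rng.random((25, 3)) < 0.2] = np.nan
        Y[:, 0] = rng.normal(size=25)
        wide = pd.DataFrame(Y, columns=["y_t0", "y_t1", "y_t2"])
        wide["group"] = "g"
        data = build_model_data(spec, wide)
        idx, th = _random_feasible_theta(spec, rng)
        ps = idx.unpack(th)
        assert casewise_loglik(data, spec, ps).sum() == pytest.approx(
            fiml_loglik(data, spec, ps), rel=1e-12)


class TestFitModel:
    def test_noise_free_recovery_is_exact(self):
        from tests.test_cohort import _noise_free_config
        cfg = _noise_free_config(slope=0.5, intercept=0.0)
        cfg = dataclasses.replace(cfg, n_carriers=20, n_noncarriers=20)
        cfg.outcomes["y"].residual_var = 1e-6
        coh = lk.generate_cohort(cfg)
        wide = lk.analysis_table(coh, ["y"], predictors=())
        spec = lk.build_univariate("y", predictors=(), zero_noncarrier_slope=False)
        with pytest.warns(UserWarning):  # tiny n per parameter
            fit = fit_model(spec, data=build_model_data(spec, wide),
                            options=FitOptions(compute_se=False))
        assert fit.estimate("alpha[y_int]|carrier") == pytest.approx(0.0, abs=1e-3)
        assert fit.estimate("alpha[y_slope]|carrier") == pytest.approx(0.5, abs=1e-3)

    def test_balanced_slope_equals_mean_ols_slope(self):
        cfg = apathy_only_config(seed=3, dropout=0.0, n_car=120, n_non=120)
        wide = m1_wide(cfg)
        spec = lk.behavioral_model(1)
        fit = fit_model(spec, build_model_data(spec, wide),
                        FitOptions(compute_se=False))
        t = np.array([0.0, 1.0, 2.0])
        car = wide[wide.group == "carrier"]
        ols = ((t - 1) @ car[["apathy_t0", "apathy_t1", "apathy_t2"]].to_numpy().T / 2)
        assert fit.estimate("alpha[apathy_slope]|carrier") == pytest.approx(
            ols.mean(), abs=1e-6)

    def test_matches_mixed_model_ml(self):
        # independent route: random intercept+slope mixed model, ML, complete data
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n, t = 120, np.array([0.0, 1.0, 2.0])
        eta = rng.multivariate_normal([1.0, 0.4], [[0.8, 0.1], [0.1, 0.2]], size=n)
        Y = eta[:, [0]] + eta[:, [1]] * t + rng.normal(0, 0.5, size=(n, 3))
        spec = base_spec("uncond", ["y"], ["all"], [])
        wide = pd.DataFrame(Y, columns=["y_t0", "y_t1", "y_t2"])
        wide["group"] = "all"
        fit = fit_model(spec, build_model_data(spec, wide))
        long = pd.DataFrame({"y": Y.ravel(), "t": np.tile(t, n),
                             "sid": np.repeat(np.arange(n), 3)})
        mixed = sm.MixedLM.from_formula("y ~ t", groups="sid", re_formula="~t",
                                        data=long).fit(reml=False, method="lbfgs")
        assert fit.loglik == pytest.approx(mixed.llf, abs=1e-5)
        assert fit.estimate("alpha[y_int]|all") == pytest.approx(
            mixed.fe_params["Intercept"], abs=1e-5)
        assert fit.estimate("alpha[y_slope]|all") == pytest.approx(
            mixed.fe_params["t"], abs=1e-5)
        assert fit.estimate("theta[y]|all") == pytest.approx(mixed.scale, abs=1e-4)

    def test_restart_robustness(self, small_fit):
        # jittered restarts land on the same maximum
        spec, data, fit = small_fit["spec"], small_fit["data"], small_fit["fit"]
        rng = np.random.default_rng(0)
        idx = ParamIndex(spec)
        lb = np.array([b[0] for b in idx.bounds])
        lls = []
        for _ in range(10):
            start = fit.theta * (1 + 0.3 * rng.standard_normal(len(fit.theta)))
            start = np.where(lb == 0, np.maximum(start, 1e-3), start)
            f = fit_model(spec, data, FitOptions(compute_se=False, start=start))
            lls.append(f.loglik)
        assert max(lls) - min(lls) < 1e-6

    def test_few_cases_per_parameter_warns(self):
        cfg = apathy_only_config(seed=1, n_car=30, n_non=30)
        wide = m1_wide(cfg)
        spec = lk.behavioral_model(1)
        with pytest.warns(UserWarning, match="cases"):
            fit_model(spec, build_model_data(spec, wide),
                      FitOptions(compute_se=False))

    def test_affine_rescaling_leaves_lrt_invariant(self):
        cfg = apathy_only_config(seed=21, n_car=120, n_non=120)
        wide = m1_wide(cfg)
        spec = lk.behavioral_model(1)
        twin = lk.equate_slopes(spec)

        def delta(w):
            d = build_model_data(spec, w)
            f = fit_model(spec, d, FitOptions(compute_se=False))
            c = fit_model(twin, d, FitOptions(
                compute_se=False, start=warm_start(twin, f)))
            return lk.lrt_compare(f, c).delta_chisq

        rescaled = wide.copy()
        for c in ["apathy_t0", "apathy_t1", "apathy_t2"]:
            rescaled[c] = 3.0 * rescaled[c] + 2.0
        assert delta(wide) == pytest.approx(delta(rescaled), abs=1e-3)


class TestStandardErrors:
    def test_z_is_estimate_over_robust_se(self, small_fit):
        fit = small_fit["fit"]
        ok = fit.se_robust > 0
        assert np.allclose(fit.z[ok], fit.theta[ok] / fit.se_robust[ok])

    def test_information_equality_under_normality(self, small_fit):
        # with correctly specified normal data, sandwich ~= inverse information
        fit = small_fit["fit"]
        ratio = fit.se_robust / fit.se_naive
        assert np.all(np.abs(ratio - 1) < 0.25)

    def test_robust_ses_valid_under_heavy_tails(self):
        # scaled-t5 residuals (excess kurtosis 6): robust CI for the residual
        # variance keeps near-nominal coverage; the naive CI undercovers.
        # (t5 rather than heavier tails: the sandwich needs a finite 4th
        # moment to be consistent for second-moment parameters.)
        rng = np.random.default_rng(99)
        t = np.array([0.0, 1.0, 2.0])
        theta_true = 0.5
        spec = base_spec("hv", ["y"], ["all"], [])
        cover_rob = cover_naive = 0
        reps = 120
        for _ in range(reps):
            n = 600
            eta = rng.multivariate_normal([0.5, 0.3], [[0.9, 0.05], [0.05, 0.15]], n)
            eps = rng.standard_t(5, size=(n, 3)) * np.sqrt(theta_true * 3.0 / 5.0)
            Y = eta[:, [0]] + eta[:, [1]] * t + eps
            wide = pd.DataFrame(Y, columns=["y_t0", "y_t1", "y_t2"])
            wide["group"] = "all"
            fit = fit_model(spec, build_model_data(spec, wide))
            est = fit.estimate("theta[y]|all")
            se_r = fit.robust_se_of("theta[y]|all")
            se_n = fit.se_naive[fit.labels.index("theta[y]|all")]
            cover_rob += abs(est - theta_true) < 1.96 * se_r
            cover_naive += abs(est - theta_true) < 1.96 * se_n
        assert 0.92 <= cover_rob / reps <= 0.98
        assert cover_naive / reps < 0.92


class TestStandardize:
    def test_unit_variance_paths_unchanged(self):
        spec = base_spec("s", ["y"], ["g"], ["x"])
        gp = lk.GroupParams(
            alpha=np.array([0.0, 0.0]),
            psi=np.array([[1.0, 0.0], [0.0, 1.0]]) - np.array([[0.25, 0], [0, 0.25]]),
            gamma=np.array([[0.5], [0.0]]), theta=np.array([0.4]),
            mu_x=np.array([0.0]), phi_x=np.array([[1.0]]))
        # total latent variance of the intercept = 0.5^2*1 + 0.75 = 1.0
        idx = ParamIndex(spec)
        fit = lk.FitResult(
            spec=spec, labels=idx.labels, theta=idx.pack(
                lk.ParameterSet(groups={"g": gp})),
            params=lk.ParameterSet(groups={"g": gp}), loglik=0.0, converged=True,
            n_iter=0, grad_norm=0.0, n_per_group={"g": 10}, n_free=idx.n_free)
        std = lk.standardize(fit)
        assert std["gamma[y_int~x]|g"] == pytest.approx(0.5)

    def test_rescaling_predictor_leaves_standardized_invariant(self):
        cfg = apathy_only_config(seed=17, n_car=150, n_non=150)
        wide = m1_wide(cfg)
        spec = lk.behavioral_model(1)
        f1 = fit_model(spec, build_model_data(spec, wide),
                       FitOptions(compute_se=False))
        wide2 = wide.copy()
        wide2["EYO"] = wide2["EYO"] * 2.0
        f2 = fit_model(spec, build_model_data(spec, wide2),
                       FitOptions(compute_se=False))
        lab = "gamma[apathy_slope~EYO]|carrier"
        assert f2.estimate(lab) == pytest.approx(f1.estimate(lab) / 2, rel=2e-2)
        assert lk.standardize(f2)[lab] == pytest.approx(
            lk.standardize(f1)[lab], abs=2e-3)
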