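"""Model fit statistics for FIML growth models.

The model chi-square is anchored at the saturated (unstructured
mean/covariance) model, whose likelihood is maximized by EM over the
missing-data patterns; the comparative fit index is anchored at the
independence baseline (free means and variances, zero covariances).
Indices follow the usual SEM conventions: RMSEA (with a 90% CI from the
noncentral chi-square), CFI, SRMR, AIC, and chi-square difference tests
for nested model pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.stats import chi2, ncx2

from .estimate import FitResult, ModelData, _LOG2PI
from .model_spec import Free, GrowthModelSpec

__all__ = [
    "FitIndices",
    "ComparisonResult",
    "saturated_loglik",
    "baseline_loglik",
    "fit_statistics",
    "lrt_compare",
    "chi2_diff_pvalue",
    "em_mvn",
]


class EMError(RuntimeError):
    """EM likelihood decreased beyond numerical tolerance (internal bug trap)."""


def _pattern_matrix(gdata) -> np.ndarray:
    """Reassemble the (n, p) data matrix (NaN = missing) of one group."""
    p = len(gdata.patterns[0].mask)
    X = np.full((gdata.n, p), np.nan)
    r = 0
    for pat in gdata.patterns:
        X[r:r + pat.n, np.where(pat.mask)[0]] = pat.rows
        r += pat.n
    return X


def _obs_loglik(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Observed-data MVN log-likelihood of a matrix with NaN missing values."""
    total = 0.0
    obs = ~np.isnan(X)
    keys = [tuple(row) for row in obs]
    for key in set(keys):
        idx = [i for i, k in enumerate(keys) if k == key]
        cols = np.where(np.array(key))[0]
        if len(cols) == 0:
            continue
        sub = sigma[np.ix_(cols, cols)]
        cf = linalg.cho_factor(sub, lower=True, check_finite=False)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        dev = X[np.ix_(idx, cols)] - mu[cols]
        z = linalg.solve_triangular(cf[0], dev.T, lower=True, check_finite=False)
        total += -0.5 * (len(idx) * (len(cols) * _LOG2PI + logdet) + (z * z).sum())
    return total


def em_mvn(X: np.ndarray, tol: float = 1e-8, max_iter: int = 500,
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """MLE of an unstructured MVN mean/covariance with missing data, by EM.

    E-step: conditional expectations of the missing entries and their
    second moments given the observed entries; M-step: closed-form update
    of the mean and covariance.  With complete data this reduces to the
    sample mean and the 1/n covariance after one iteration.

    Returns (mu, sigma, maximized observed-data log-likelihood).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        raise ValueError("rows with no observed entries are not allowed")
    mu = np.array([X[obs[:, j], j].mean() if obs[:, j].any() else 0.0 for j in range(p)])
    var = np.array([X[obs[:, j], j].var() if obs[:, j].sum() > 1 else 1.0 for j in range(p)])
    sigma = np.diag(np.maximum(var, 1e-8))

    patterns: dict[tuple, list[int]] = {}
    for i, row in enumerate(obs):
        patterns.setdefault(tuple(row), []).append(i)

    ll_prev = -np.inf
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        for key, idx in patterns.items():
            o = np.where(np.array(key))[0]
            m = np.where(~np.array(key))[0]
            rows = X[np.ix_(idx, o)]
            if len(m) == 0:
                T1 += rows.sum(axis=0)
                T2 += rows.T @ rows
                continue
            soo = sigma[np.ix_(o, o)]
            som = sigma[np.ix_(o, m)]
            cf = linalg.cho_factor(soo, lower=True, check_finite=False)
            reg = linalg.cho_solve(cf, som, check_finite=False)  # soo^-1 som
            cond_cov = sigma[np.ix_(m, m)] - som.T @ reg
            fill = mu[m] + (rows - mu[o]) @ reg  # E[y_m | y_o]
            comp = np.zeros((len(idx), p))
            comp[:, o] = rows
            comp[:, m] = fill
            T1 += comp.sum(axis=0)
            T2 += comp.T @ comp
            T2[np.ix_(m, m)] += len(idx) * cond_cov
        mu_new = T1 / n
        sigma_new = T2 / n - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        mu, sigma = mu_new, sigma_new
        ll = _obs_loglik(X, mu, sigma)
        if ll < ll_prev - 1e-6 * max(1.0, abs(ll_prev)):
            raise EMError(f"EM log-likelihood decreased: {ll_prev} -> {ll}")
        if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            ll_prev = ll
            break
        ll_prev = ll
    return mu, sigma, ll_prev


def saturated_loglik(data: ModelData) -> float:
    """Group-wise saturated (unstructured MVN) maximized log-likelihood."""
    return sum(m["loglik"] for m in _saturated(data).values())


def _saturated(data: ModelData) -> dict:
    """Cache of per-group saturated moments and log-likelihood."""
    if data._saturated is None:
        out = {}
        for g, gdata in data.groups.items():
            mu, sigma, ll = em_mvn(_pattern_matrix(gdata))
            out[g] = {"mu": mu, "sigma": sigma, "loglik": ll}
        data._saturated = out
    return data._saturated


def baseline_loglik(data: ModelData) -> tuple[float, int]:
    """Independence-model log-likelihood and its free-parameter count.

    Free means and variances per variable and group, all covariances
    fixed at 0: under independence the FIML likelihood factorizes over
    variables, so each variable's MLE is the mean and 1/n variance of its
    observed values.
    """
    total = 0.0
    n_params = 0
    for gdata in data.groups.values():
        X = _pattern_matrix(gdata)
        for j in range(X.shape[1]):
            v = X[~np.isnan(X[:, j]), j]
            nj = len(v)
            if nj < 2:
                raise ValueError(f"variable {j} has fewer than 2 observed values")
            s2 = v.var()
            if s2 <= 0:
                raise ValueError(f"variable {j} has zero variance")
            total += -0.5 * nj * (_LOG2PI + np.log(s2) + 1.0)
            n_params += 2
    return total, n_params


@dataclass
class FitIndices:
    chisq: float
    df: int
    pvalue: float
    chisq_per_df: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    srmr: float
    aic: float
    loglik: float
    n_total: int
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "chisq": self.chisq, "df": self.df, "pvalue": self.pvalue,
            "chisq_per_df": self.chisq_per_df, "rmsea": self.rmsea,
            "rmsea_ci_lower": self.rmsea_ci[0], "rmsea_ci_upper": self.rmsea_ci[1],
            "cfi": self.cfi, "srmr": self.srmr, "aic": self.aic,
            "loglik": self.loglik, "n": self.n_total,
        }


def _rmsea_ci(chisq: float, df: int, N: int, G: int, conf: float = 0.90
              ) -> tuple[float, float]:
    """90% CI for RMSEA by inverting the noncentral chi-square CDF in the
    noncentrality parameter."""
    lo_q, hi_q = (1 + conf) / 2, (1 - conf) / 2  # 0.95, 0.05

    def to_rmsea(lam: float) -> float:
        return float(np.sqrt(G * max(lam, 0.0) / (df * N)))

    def solve(target: float) -> float | None:
        # find lambda with ncx2.cdf(chisq, df, lambda) = target (cdf decreasing in lambda)
        if ncx2.cdf(chisq, df, 1e-10) < target:
            return None  # even lambda=0 has cdf below target
        hi = max(chisq, 1.0)
        while ncx2.cdf(chisq, df, hi) > target:
            hi *= 2
            if hi > 1e8:
                return None
        return float(optimize.brentq(
            lambda lam: ncx2.cdf(chisq, df, lam) - target, 1e-10, hi, xtol=1e-8))

    lam_lo = solve(lo_q)
    lam_hi = solve(hi_q)
    lower = 0.0 if lam_lo is None else to_rmsea(lam_lo)
    upper = 0.0 if lam_hi is None else to_rmsea(lam_hi)
    return (lower, max(lower, upper))


def _srmr(fit: FitResult, data: ModelData) -> float:
    """Root of the mean squared standardized residual of covariances and
    means, averaged over groups; the saturated EM moments act as the
    sample moments under missingness."""
    from .estimate import implied_moments

    sat = _saturated(data)
    vals = []
    for g in fit.spec.groups:
        s_mu, s_sigma = sat[g]["mu"], sat[g]["sigma"]
        m_mu, m_sigma = implied_moments(fit.spec, fit.params[g])
        sd = np.sqrt(np.clip(np.diag(s_sigma), 1e-12, None))
        resid = []
        p = len(s_mu)
        for i in range(p):
            resid.append((s_mu[i] - m_mu[i]) / sd[i])
            for j in range(i, p):
                resid.append((s_sigma[i, j] - m_sigma[i, j]) / (sd[i] * sd[j]))
        vals.append(np.sqrt(np.mean(np.square(resid))))
    return float(np.mean(vals))


def fit_statistics(fit: FitResult, data: ModelData) -> FitIndices:
    """Chi-square, RMSEA (+90% CI), CFI, SRMR, AIC for a converged fit."""
    ll_sat = saturated_loglik(data)
    chisq = max(2.0 * (ll_sat - fit.loglik), 0.0)
    df = fit.spec.df
    N = fit.n_total
    G = len(fit.spec.groups)
    if df <= 0:
        return FitIndices(
            chisq=chisq, df=df, pvalue=np.nan, chisq_per_df=np.nan, rmsea=np.nan,
            rmsea_ci=(np.nan, np.nan), cfi=np.nan, srmr=_srmr(fit, data),
            aic=fit.aic, loglik=fit.loglik, n_total=N, defined=False)
    pvalue = float(chi2.sf(chisq, df))
    rmsea = float(np.sqrt(G) * np.sqrt(max(chisq - df, 0.0) / (df * N)))
    rmsea_ci = _rmsea_ci(chisq, df, N, G)

    ll_base, k_base = baseline_loglik(data)
    p = fit.spec.n_observed
    df_base = G * (p * (p + 3) // 2) - k_base
    chisq_base = max(2.0 * (ll_sat - ll_base), 0.0)
    denom = max(chisq_base - df_base, chisq - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chisq - df, 0.0) / denom
    return FitIndices(
        chisq=chisq, df=df, pvalue=pvalue, chisq_per_df=chisq / df,
        rmsea=rmsea, rmsea_ci=rmsea_ci, cfi=float(np.clip(cfi, 0.0, 1.0)),
        srmr=_srmr(fit, data), aic=fit.aic, loglik=fit.loglik, n_total=N)


# ----------------------------------------------------------------------
# nested-model comparison
# ----------------------------------------------------------------------

@dataclass
class ComparisonResult:
    delta_chisq: float
    delta_df: int
    pvalue: float
    delta_aic: float
    preferred: str  # name of the AIC-preferred model

    def to_dict(self) -> dict:
        return {"delta_chisq": self.delta_chisq, "delta_df": self.delta_df,
                "pvalue": self.pvalue, "delta_aic": self.delta_aic,
                "preferred": self.preferred}


def chi2_diff_pvalue(delta_chisq: float, delta_df: int) -> float:
    """Upper-tail probability of the central chi-square difference test."""
    if delta_df < 1:
        raise ValueError("delta_df must be >= 1")
    return float(chi2.sf(max(delta_chisq, 0.0), delta_df))


def _check_nested(free: GrowthModelSpec, constrained: GrowthModelSpec) -> None:
    if free.outcomes != constrained.outcomes or free.groups != constrained.groups \
            or free.predictors != constrained.predictors or free.n_waves != constrained.n_waves:
        raise ValueError("models are not on the same observed variables/groups")
    for key in free.param_keys():
        for g in free.groups:
            if isinstance(constrained.params[key][g], Free) \
                    and not isinstance(free.params[key][g], Free):
                raise ValueError(f"constrained model frees {key} in {g}, free model does not")
    if constrained.n_free > free.n_free:
        raise ValueError("constrained model is not more restrictive")
    if constrained.n_free == free.n_free and constrained.params != free.params:
        raise ValueError("models have equal free counts but differ: not nested")


def lrt_compare(free_fit: FitResult, constrained_fit: FitResult) -> ComparisonResult:
    """Likelihood-ratio test of a constrained model nested in a free one.

    Delta chi-square = 2 (ll_free - ll_constrained); the p-value uses the
    central chi-square with Delta df = difference in free-parameter counts.
    """
    _check_nested(free_fit.spec, constrained_fit.spec)
    d_chisq = max(2.0 * (free_fit.loglik - constrained_fit.loglik), 0.0)
    d_df = free_fit.n_free - constrained_fit.n_free
    p = 1.0 if d_df == 0 else chi2_diff_pvalue(d_chisq, d_df)
    d_aic = free_fit.aic - constrained_fit.aic
    preferred = free_fit.spec.name if d_aic < 0 else constrained_fit.spec.name
    return ComparisonResult(delta_chisq=d_chisq, delta_df=d_df, pvalue=p,
                            delta_aic=d_aic, preferred=preferred)
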