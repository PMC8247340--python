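"""Full-information maximum likelihood estimation of growth models.

Estimation treats each subject's observed sub-vector (outcome waves plus
exogenous predictors) as multivariate normal with the model-implied mean
and covariance; subjects with missing waves contribute the marginal
density of whatever they were observed on (FIML).  Standard errors come
in two flavours: naive (inverse observed information) and robust sandwich
A^-1 B A^-1 built from casewise scores, which remains valid under
non-normality and missingness at random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.linalg import lapack

from .model_spec import Free, GroupParams, GrowthModelSpec, ParameterSet, SpecError

__all__ = [
    "ModelData",
    "FitOptions",
    "FitResult",
    "build_model_data",
    "implied_moments",
    "fiml_loglik",
    "fit_model",
    "standardize",
]

_LOG2PI = np.log(2.0 * np.pi)
_PENALTY = 1e12  # objective value returned for infeasible (non-PD) parameters
_BOUND_TOL = 1e-6  # a free variance below this is flagged as an improper solution


# ----------------------------------------------------------------------
# data containers
# ----------------------------------------------------------------------

@dataclass
class PatternBlock:
    """Rows of one group sharing a missing-data pattern."""

    mask: np.ndarray  # (p,) bool, True = observed
    rows: np.ndarray  # (n_p, n_obs) observed values only
    n: int
    mean: np.ndarray  # (n_obs,) pattern mean
    scatter: np.ndarray  # (n_obs, n_obs) sum of centered outer products
    idx: np.ndarray | None = None  # observed column indices
    grid: tuple | None = None  # open-mesh index for sigma sub-selection


@dataclass
class GroupData:
    name: str
    patterns: list[PatternBlock]
    n: int


@dataclass
class ModelData:
    """Observed data arranged by group and missing-data pattern."""

    groups: dict[str, GroupData]
    observed_names: tuple[str, ...]
    _saturated: dict | None = field(default=None, repr=False)

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups.values())


def build_model_data(spec: GrowthModelSpec, wide: pd.DataFrame,
                     group_col: str = "group") -> ModelData:
    """Arrange a wide analysis table into per-group missing-data patterns.

    `wide` must contain one row per subject with the columns named by
    ``spec.observed_names()`` plus a group label column.  Rows observed on
    no variable are dropped.
    """
    cols = list(spec.observed_names())
    missing_cols = [c for c in cols if c not in wide.columns]
    if missing_cols:
        raise KeyError(f"analysis table lacks columns {missing_cols}")
    groups: dict[str, GroupData] = {}
    for g in spec.groups:
        sub = wide.loc[wide[group_col] == g, cols]
        X = sub.to_numpy(dtype=float)
        obs = ~np.isnan(X)
        keep = obs.any(axis=1)
        X, obs = X[keep], obs[keep]
        if X.shape[0] < 2:
            raise ValueError(f"group '{g}' has fewer than 2 usable rows")
        patterns: list[PatternBlock] = []
        keys = [tuple(row) for row in obs]
        for key in sorted(set(keys), reverse=True):
            idx = [i for i, k in enumerate(keys) if k == key]
            mask = np.array(key, dtype=bool)
            cols_obs = np.where(mask)[0]
            rows = X[np.ix_(idx, cols_obs)]
            mean = rows.mean(axis=0)
            dev = rows - mean
            patterns.append(PatternBlock(
                mask=mask, rows=rows, n=len(idx), mean=mean,
                scatter=dev.T @ dev, idx=cols_obs,
                grid=np.ix_(cols_obs, cols_obs)))
        groups[g] = GroupData(name=g, patterns=patterns, n=X.shape[0])
    return ModelData(groups=groups, observed_names=tuple(cols))


# ----------------------------------------------------------------------
# implied moments
# ----------------------------------------------------------------------

def implied_moments(spec: GrowthModelSpec, gp: GroupParams) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean and covariance of the full observed vector.

    The observed vector stacks the outcome waves and the exogenous
    predictors.  With eta = alpha + Gamma (x - mu_x) + zeta,

        E[y] = Lambda alpha,                 E[x] = mu_x
        cov(y) = Lambda (Gamma Phi Gamma' + Psi) Lambda' + Theta diag
        cov(y, x) = Lambda Gamma Phi,        cov(x) = Phi.
    """
    lam = spec.loading_matrix()
    W = spec.n_waves
    k = spec.n_factors
    q = spec.n_predictors
    if gp.alpha.shape != (k,) or gp.psi.shape != (k, k) or gp.gamma.shape != (k, q):
        raise SpecError("parameter dimensions inconsistent with spec")
    v_eta = gp.gamma @ gp.phi_x @ gp.gamma.T + gp.psi
    ny = lam.shape[0]
    p = ny + q
    mu = np.empty(p)
    mu[:ny] = lam @ gp.alpha
    mu[ny:] = gp.mu_x
    sigma = np.empty((p, p))
    syy = lam @ v_eta @ lam.T
    theta_diag = np.repeat(gp.theta, W)
    syy[np.diag_indices(ny)] += theta_diag
    syx = lam @ gp.gamma @ gp.phi_x
    sigma[:ny, :ny] = syy
    sigma[:ny, ny:] = syx
    sigma[ny:, :ny] = syx.T
    sigma[ny:, ny:] = gp.phi_x
    return mu, 0.5 * (sigma + sigma.T)


# ----------------------------------------------------------------------
# parameter packing
# ----------------------------------------------------------------------

class ParamIndex:
    """Maps the free-parameter vector onto the per-group parameter arrays.

    Unpacking is vectorized: all parameter matrices live in one flat
    template buffer (fixed values pre-filled) and the free values are
    scattered into it with a single fancy-indexing assignment.
    """

    def __init__(self, spec: GrowthModelSpec):
        self.spec = spec
        self.labels = spec.free_labels()
        self.pos = {lab: i for i, lab in enumerate(self.labels)}
        self.bounds: list[tuple[float, float]] = [(-np.inf, np.inf)] * len(self.labels)
        # slot list: (key, group, status)
        self.slots: list[tuple[tuple, str, object]] = []
        for key in spec.param_keys():
            for g in spec.groups:
                st = spec.params[key][g]
                self.slots.append((key, g, st))
                if isinstance(st, Free) and spec.is_variance(key):
                    self.bounds[self.pos[st.label]] = (0.0, np.inf)
        self._build_flat_map()

    def _build_flat_map(self) -> None:
        spec = self.spec
        k, q, no = spec.n_factors, spec.n_predictors, spec.n_outcomes
        sizes = {"alpha": k, "psi": k * k, "gamma": k * q,
                 "theta": no, "mu_x": q, "phi_x": q * q}
        per_group = sum(sizes.values())
        self._offsets: dict[str, dict[str, int]] = {}
        base = 0
        for g in spec.groups:
            off, cur = {}, base
            for name in ("alpha", "psi", "gamma", "theta", "mu_x", "phi_x"):
                off[name] = cur
                cur += sizes[name]
            self._offsets[g] = off
            base += per_group
        self._flat_template = np.zeros(base)
        pred_pos = {p: j for j, p in enumerate(spec.predictors)}
        out_pos = {o: j for j, o in enumerate(spec.outcomes)}
        scatter_pos, scatter_src = [], []
        for key, g, st in self.slots:
            off = self._offsets[g]
            kind = key[0]
            if kind == "alpha":
                flats = [off["alpha"] + key[1]]
            elif kind == "psi":
                i, j = key[1], key[2]
                flats = [off["psi"] + i * k + j]
                if i != j:
                    flats.append(off["psi"] + j * k + i)
            elif kind == "gamma":
                flats = [off["gamma"] + key[1] * q + pred_pos[key[2]]]
            elif kind == "theta":
                flats = [off["theta"] + out_pos[key[1]]]
            elif kind == "mu_x":
                flats = [off["mu_x"] + pred_pos[key[1]]]
            else:
                i, j = key[1], key[2]
                flats = [off["phi_x"] + i * q + j]
                if i != j:
                    flats.append(off["phi_x"] + j * q + i)
            if isinstance(st, Free):
                scatter_pos.extend(flats)
                scatter_src.extend([self.pos[st.label]] * len(flats))
            else:
                self._flat_template[flats] = st.value
        self._scatter_pos = np.array(scatter_pos, dtype=int)
        self._scatter_src = np.array(scatter_src, dtype=int)

    @property
    def n_free(self) -> int:
        return len(self.labels)

    def unpack(self, theta: np.ndarray) -> ParameterSet:
        spec = self.spec
        k, q, no = spec.n_factors, spec.n_predictors, spec.n_outcomes
        flat = self._flat_template.copy()
        flat[self._scatter_pos] = np.asarray(theta)[self._scatter_src]
        out: dict[str, GroupParams] = {}
        for g in spec.groups:
            off = self._offsets[g]
            out[g] = GroupParams(
                alpha=flat[off["alpha"]:off["alpha"] + k],
                psi=flat[off["psi"]:off["psi"] + k * k].reshape(k, k),
                gamma=flat[off["gamma"]:off["gamma"] + k * q].reshape(k, q),
                theta=flat[off["theta"]:off["theta"] + no],
                mu_x=flat[off["mu_x"]:off["mu_x"] + q],
                phi_x=flat[off["phi_x"]:off["phi_x"] + q * q].reshape(q, q),
            )
        return ParameterSet(groups=out)

    def pack(self, params: ParameterSet) -> np.ndarray:
        spec = self.spec
        theta = np.zeros(self.n_free)
        pred_pos = {p: j for j, p in enumerate(spec.predictors)}
        out_pos = {o: j for j, o in enumerate(spec.outcomes)}
        for key, g, st in self.slots:
            if not isinstance(st, Free):
                continue
            gp = params[g]
            kind = key[0]
            if kind == "alpha":
                val = gp.alpha[key[1]]
            elif kind == "psi":
                val = gp.psi[key[1], key[2]]
            elif kind == "gamma":
                val = gp.gamma[key[1], pred_pos[key[2]]]
            elif kind == "theta":
                val = gp.theta[out_pos[key[1]]]
            elif kind == "mu_x":
                val = gp.mu_x[pred_pos[key[1]]]
            else:
                val = gp.phi_x[key[1], key[2]]
            theta[self.pos[st.label]] = val
        return theta


# ----------------------------------------------------------------------
# likelihood
# ----------------------------------------------------------------------

def _group_loglik(spec: GrowthModelSpec, gp: GroupParams, gdata: GroupData) -> float:
    mu, sigma = implied_moments(spec, gp)
    total = 0.0
    for pat in gdata.patterns:
        sub = sigma[pat.grid]
        c, info = lapack.dpotrf(sub, lower=1)
        if info != 0:
            return -np.inf
        logdet = 2.0 * np.log(np.diagonal(c)).sum()
        d = pat.mean - mu[pat.idx]
        k = len(pat.idx)
        rhs = np.empty((k, k + 1))
        rhs[:, 0] = d
        rhs[:, 1:] = pat.scatter
        sol, info = lapack.dpotrs(c, rhs, lower=1)
        quad = pat.n * (d @ sol[:, 0]) + np.trace(sol[:, 1:])
        total += -0.5 * (pat.n * (k * _LOG2PI + logdet) + quad)
    return total


def fiml_loglik(data: ModelData, spec: GrowthModelSpec, params: ParameterSet) -> float:
    """FIML log-likelihood: sum over groups and missing-data patterns.

    Returns -inf when the implied covariance of any observed sub-vector is
    not positive definite, signalling an infeasible point to the optimizer.
    """
    total = 0.0
    for g, gdata in data.groups.items():
        total += _group_loglik(spec, params[g], gdata)
        if not np.isfinite(total):
            return -np.inf
    return total


def casewise_loglik(data: ModelData, spec: GrowthModelSpec, params: ParameterSet) -> np.ndarray:
    """Per-subject log-likelihood contributions, in fixed (group, pattern, row) order."""
    out = []
    for g, gdata in data.groups.items():
        mu, sigma = implied_moments(spec, params[g])
        for pat in gdata.patterns:
            sub = sigma[pat.grid]
            c, info = lapack.dpotrf(sub, lower=1)
            if info != 0:
                raise linalg.LinAlgError("implied covariance not positive definite")
            logdet = 2.0 * np.log(np.diagonal(c)).sum()
            dev = pat.rows - mu[pat.idx]
            z, info = lapack.dtrtrs(c, dev.T, lower=1)
            quad = (z * z).sum(axis=0)
            out.append(-0.5 * (len(pat.idx) * _LOG2PI + logdet + quad))
    return np.concatenate(out)


# ----------------------------------------------------------------------
# starting values
# ----------------------------------------------------------------------

def _start_values(spec: GrowthModelSpec, data: ModelData, index: ParamIndex
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic moment-based starting values and parameter scales.

    Intercept/slope means from an OLS fit of the observed wave means on
    wave times; latent variances and the residual variance split the
    baseline variance; predictor moments from their observed values.  The
    scale vector gives each parameter's natural order of magnitude (e.g.
    sd_i * sd_j for a covariance) so the optimizer can work on an O(1)
    parametrization even when a parameter starts at zero.
    """
    W = spec.n_waves
    t = np.asarray(spec.wave_times[:W])
    cols = spec.observed_names()
    starts: dict[str, list[float]] = {lab: [] for lab in index.labels}
    scales: dict[str, list[float]] = {lab: [] for lab in index.labels}

    for g in spec.groups:
        gdata = data.groups[g]
        p = len(cols)
        # reassemble a masked matrix for column moments
        n = gdata.n
        X = np.full((n, p), np.nan)
        r = 0
        for pat in gdata.patterns:
            X[r:r + pat.n, np.where(pat.mask)[0]] = pat.rows
            r += pat.n
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(X, axis=0)
            col_var = np.nanvar(X, axis=0, ddof=1)
        col_mean = np.nan_to_num(col_mean)
        col_var = np.where(np.isfinite(col_var) & (col_var > 0), col_var, 1.0)

        gp_start = GroupParams(
            alpha=np.zeros(spec.n_factors),
            psi=np.zeros((spec.n_factors, spec.n_factors)),
            gamma=np.zeros((spec.n_factors, spec.n_predictors)),
            theta=np.zeros(spec.n_outcomes),
            mu_x=np.zeros(spec.n_predictors),
            phi_x=np.zeros((spec.n_predictors, spec.n_predictors)),
        )
        design = np.column_stack([np.ones(W), t])
        out_sd = np.ones(spec.n_outcomes)
        for m, out in enumerate(spec.outcomes):
            wave_means = col_mean[m * W:(m + 1) * W]
            coef, *_ = np.linalg.lstsq(design, wave_means, rcond=None)
            v0 = col_var[m * W]
            out_sd[m] = np.sqrt(v0)
            gp_start.alpha[2 * m] = coef[0]
            gp_start.alpha[2 * m + 1] = coef[1]
            gp_start.psi[2 * m, 2 * m] = 0.5 * v0
            gp_start.psi[2 * m + 1, 2 * m + 1] = 0.05 * v0
            gp_start.theta[m] = 0.5 * v0
        ny = spec.n_outcomes * W
        for j in range(spec.n_predictors):
            gp_start.mu_x[j] = col_mean[ny + j]
            gp_start.phi_x[j, j] = col_var[ny + j]
        # pairwise-complete covariances between predictors as starts
        for i in range(spec.n_predictors):
            for j in range(i + 1, spec.n_predictors):
                xi, xj = X[:, ny + i], X[:, ny + j]
                both = ~(np.isnan(xi) | np.isnan(xj))
                if both.sum() > 2:
                    cv = float(np.cov(xi[both], xj[both], ddof=1)[0, 1])
                    gp_start.phi_x[i, j] = gp_start.phi_x[j, i] = cv

        lat_sd = np.sqrt(np.diag(gp_start.psi) + 1e-12)
        x_sd = np.sqrt(np.diag(gp_start.phi_x))
        pred_pos = {pp: jj for jj, pp in enumerate(spec.predictors)}
        out_pos = {oo: jj for jj, oo in enumerate(spec.outcomes)}
        for key, gg, st in index.slots:
            if gg != g or not isinstance(st, Free):
                continue
            kind = key[0]
            if kind == "alpha":
                val = gp_start.alpha[key[1]]
                sc = out_sd[key[1] // 2]
            elif kind == "psi":
                i, j = key[1], key[2]
                val = gp_start.psi[i, j]
                sc = lat_sd[i] * lat_sd[j]
            elif kind == "gamma":
                i, pp = key[1], pred_pos[key[2]]
                val = gp_start.gamma[i, pp]
                sc = lat_sd[i] / max(x_sd[pp], 1e-8)
            elif kind == "theta":
                val = gp_start.theta[out_pos[key[1]]]
                sc = val
            elif kind == "mu_x":
                pp = pred_pos[key[1]]
                val = gp_start.mu_x[pp]
                sc = max(abs(val), x_sd[pp])
            else:
                i, j = key[1], key[2]
                val = gp_start.phi_x[i, j]
                sc = x_sd[i] * x_sd[j]
            starts[st.label].append(val)
            scales[st.label].append(sc)

    theta0 = np.zeros(index.n_free)
    scale0 = np.full(index.n_free, 0.1)
    for lab in index.labels:
        i = index.pos[lab]
        if starts[lab]:
            theta0[i] = float(np.mean(starts[lab]))
            scale0[i] = max(float(np.mean(scales[lab])), 1e-3)
    # keep variances strictly inside the bound at the start
    for i, (lo, _) in enumerate(index.bounds):
        if lo == 0.0:
            theta0[i] = max(theta0[i], 1e-3 * scale0[i])
    return theta0, scale0


# ----------------------------------------------------------------------
# numerical derivatives
# ----------------------------------------------------------------------

def _fd_steps(theta: np.ndarray) -> np.ndarray:
    return np.cbrt(np.finfo(float).eps) * np.maximum(1.0, np.abs(theta))


def numerical_hessian(f, theta: np.ndarray, lower_bounds: np.ndarray) -> np.ndarray:
    """Central-difference Hessian; evaluation points are kept feasible by
    shifting the center away from an active lower bound."""
    h = _fd_steps(theta)
    x0 = np.maximum(theta, lower_bounds + h)  # shift off active bounds
    n = len(theta)
    H = np.zeros((n, n))
    f0 = f(x0)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = f(x0 + 2 * ei)
        fmm = f(x0 - 2 * ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (4 * h[i] ** 2)
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def casewise_scores(data: ModelData, spec: GrowthModelSpec, index: ParamIndex,
                    theta: np.ndarray) -> np.ndarray:
    """(n_cases, n_free) matrix of per-subject score vectors (central differences)."""
    h = _fd_steps(theta)
    lb = np.array([b[0] for b in index.bounds])
    x0 = np.maximum(theta, lb + h)
    cols = []
    for i in range(len(theta)):
        step = np.zeros_like(theta)
        step[i] = h[i]
        lp = casewise_loglik(data, spec, index.unpack(x0 + step))
        lm = casewise_loglik(data, spec, index.unpack(x0 - step))
        cols.append((lp - lm) / (2 * h[i]))
    return np.column_stack(cols)


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

@dataclass
class FitOptions:
    max_iter: int = 500
    gtol: float = 1e-6
    compute_se: bool = True
    start: np.ndarray | None = None
    warn_cases_per_param: bool = True


@dataclass
class FitResult:
    """Converged (or not) FIML fit of a growth-model specification."""

    spec: GrowthModelSpec
    labels: list[str]
    theta: np.ndarray
    params: ParameterSet
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    n_per_group: dict[str, int]
    n_free: int
    se_naive: np.ndarray | None = None
    se_robust: np.ndarray | None = None
    se_warning: bool = False
    improper: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return sum(self.n_per_group.values())

    @property
    def z(self) -> np.ndarray:
        """z-values: estimate / robust SE (NaN where the SE is 0 or absent)."""
        if self.se_robust is None:
            return np.full_like(self.theta, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se_robust > 0, self.theta / self.se_robust, np.nan)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_free

    def estimate(self, label: str) -> float:
        return float(self.theta[self.labels.index(label)])

    def robust_se_of(self, label: str) -> float:
        return float(self.se_robust[self.labels.index(label)])

    def summary_frame(self) -> pd.DataFrame:
        from scipy.stats import norm

        df = pd.DataFrame({"label": self.labels, "estimate": self.theta})
        if self.se_naive is not None:
            df["se_naive"] = self.se_naive
        if self.se_robust is not None:
            df["se_robust"] = self.se_robust
            df["z"] = self.z
            df["p"] = 2.0 * norm.sf(np.abs(self.z))
        std = standardize(self)
        df["std_estimate"] = [std.get(lab, np.nan) for lab in self.labels]
        return df


def fit_model(spec: GrowthModelSpec, data: ModelData,
              options: FitOptions | None = None) -> FitResult:
    """Maximize the FIML log-likelihood by quasi-Newton (L-BFGS-B) iteration.

    Starting values are deterministic and moment-based; free variances are
    box-constrained at zero and flagged as improper solutions when the
    optimum lies on the bound.
    """
    options = options or FitOptions()
    spec.validate()
    index = ParamIndex(spec)
    if index.n_free == 0:
        raise SpecError("model has no free parameters")
    n_total = sum(g.n for g in data.groups.values())
    if options.warn_cases_per_param and n_total < 5 * index.n_free:
        warnings.warn(
            f"only {n_total} cases for {index.n_free} free parameters "
            "(< 5 cases per parameter)", UserWarning)

    def negll(theta: np.ndarray) -> float:
        ll = fiml_loglik(data, spec, index.unpack(theta))
        return _PENALTY if not np.isfinite(ll) else -ll

    theta0, scale0 = _start_values(spec, data, index)
    if options.start is not None:
        theta0 = np.asarray(options.start, dtype=float)
    # diagonal preconditioning: optimize on a scale where every parameter is O(1)
    scale = np.maximum(np.abs(theta0), scale0)
    z0 = theta0 / scale
    z_bounds = [(lo / s if np.isfinite(lo) else lo, hi)
                for (lo, hi), s in zip(index.bounds, scale)]
    opts = {"maxiter": options.max_iter, "ftol": 1e-14, "gtol": options.gtol,
            "maxfun": 200000}
    z_lb = np.array([b[0] for b in z_bounds])

    def projected_grad_norm(res) -> float:
        if res.jac is None:
            return np.inf
        g = np.array(res.jac, dtype=float)
        at_lb = np.isfinite(z_lb) & (res.x <= z_lb + 1e-10)
        g[at_lb & (g > 0)] = 0.0  # bound active and pushing outward
        return float(np.max(np.abs(g)))

    # L-BFGS-B restarted with fresh curvature memory until the projected
    # gradient is small: a line search that strays into the infeasible
    # (non-PD) penalty region can corrupt the quasi-Newton memory and stall
    # the first pass far from the optimum.
    x, prev_fun, n_total_iter, converged = z0, np.inf, 0, False
    res = None
    for _ in range(40):
        res = optimize.minimize(lambda z: negll(z * scale), x,
                                method="L-BFGS-B", bounds=z_bounds, options=opts)
        n_total_iter += res.nit
        x = res.x
        gnorm = projected_grad_norm(res)
        if gnorm <= 1e-5 * max(1.0, abs(res.fun)):
            converged = True
            break
        if prev_fun - res.fun <= 1e-12 * max(1.0, abs(res.fun)):
            # stalled with a large gradient: deterministic nudge off the point
            bump = 1e-3 * np.where(np.arange(len(x)) % 2 == 0, 1.0, -1.0)
            x = np.where(np.isfinite(z_lb),
                         np.maximum(x + bump * np.maximum(np.abs(x), 0.1), z_lb + 1e-8),
                         x + bump * np.maximum(np.abs(x), 0.1))
        prev_fun = res.fun

    theta_hat = res.x * scale
    grad_norm = projected_grad_norm(res)
    params = index.unpack(theta_hat)
    loglik = fiml_loglik(data, spec, params)

    improper = [lab for i, lab in enumerate(index.labels)
                if index.bounds[i][0] == 0.0 and theta_hat[i] < _BOUND_TOL]

    fit = FitResult(
        spec=spec, labels=index.labels, theta=theta_hat, params=params,
        loglik=loglik, converged=converged, n_iter=int(n_total_iter),
        grad_norm=grad_norm, n_per_group={g: d.n for g, d in data.groups.items()},
        n_free=index.n_free, improper=improper,
    )
    if options.compute_se and converged:
        _attach_standard_errors(fit, data, index)
    return fit


def _attach_standard_errors(fit: FitResult, data: ModelData, index: ParamIndex) -> None:
    """Naive (inverse information) and sandwich standard errors.

    A is the observed information (negative Hessian of the total
    log-likelihood), B the sum of casewise score outer products; the
    sandwich covariance is A^-1 B A^-1.
    """
    lb = np.array([b[0] for b in index.bounds])

    def negll(theta: np.ndarray) -> float:
        ll = fiml_loglik(data, fit.spec, index.unpack(theta))
        return _PENALTY if not np.isfinite(ll) else -ll

    A = numerical_hessian(negll, fit.theta, lb)
    S = casewise_scores(data, fit.spec, index, fit.theta)
    B = S.T @ S
    warn = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", linalg.LinAlgWarning)
            A_inv = linalg.inv(A)
        if not np.all(np.isfinite(A_inv)):
            raise linalg.LinAlgError
    except (linalg.LinAlgError, linalg.LinAlgWarning):
        A_inv = linalg.pinv(A)
        warn = True
    cov_naive = A_inv
    cov_robust = A_inv @ B @ A_inv
    with np.errstate(invalid="ignore"):
        fit.se_naive = np.sqrt(np.clip(np.diag(cov_naive), 0, None))
        fit.se_robust = np.sqrt(np.clip(np.diag(cov_robust), 0, None))
    fit.se_warning = warn


def refit_constrained(fit: FitResult, data: ModelData,
                      options: FitOptions | None = None,
                      max_rounds: int = 3) -> FitResult:
    """Flag-then-constrain handling of improper solutions.

    While any free variance sits on its zero bound, refit with that
    parameter fixed at 0 (the standard remedy for negative-variance /
    boundary solutions in growth models).
    """
    current = fit
    for _ in range(max_rounds):
        if not current.improper:
            return current
        spec = current.spec
        for lab in current.improper:
            for key in spec.param_keys():
                for g in spec.groups:
                    st = spec.params[key][g]
                    if isinstance(st, Free) and st.label == lab and spec.is_variance(key):
                        spec = spec.fix(key, 0.0)
        spec.name = current.spec.name
        current = fit_model(spec, data, options)
    return current


# ----------------------------------------------------------------------
# standardization
# ----------------------------------------------------------------------

def standardize(fit: FitResult) -> dict[str, float]:
    """Standardized estimates for each free parameter label.

    Paths are multiplied by the model-implied SD of the source and divided
    by the SD of the target; covariances become correlations; means are
    divided by the relevant SD.  Latent SDs use the total implied factor
    variance diag(Gamma Phi Gamma' + Psi).  For an equated label the first
    group in which it appears supplies the implied moments.
    """
    spec = fit.spec
    out: dict[str, float] = {}
    pred_pos = {p: j for j, p in enumerate(spec.predictors)}
    out_pos = {o: j for j, o in enumerate(spec.outcomes)}
    for g in spec.groups:
        gp = fit.params[g]
        v_eta = gp.gamma @ gp.phi_x @ gp.gamma.T + gp.psi
        sd_eta = np.sqrt(np.clip(np.diag(v_eta), 0, None))
        sd_x = np.sqrt(np.clip(np.diag(gp.phi_x), 0, None))
        _, sigma = implied_moments(spec, gp)
        sd_y0 = {out: np.sqrt(max(sigma[m * spec.n_waves, m * spec.n_waves], 0.0))
                 for m, out in enumerate(spec.outcomes)}
        for key in spec.param_keys():
            st = spec.params[key][g]
            if not isinstance(st, Free) or st.label in out:
                continue
            est = fit.theta[fit.labels.index(st.label)]
            kind = key[0]
            val = np.nan
            if kind == "alpha":
                val = est / sd_eta[key[1]] if sd_eta[key[1]] > 0 else np.nan
            elif kind == "psi":
                i, j = key[1], key[2]
                denom = sd_eta[i] * sd_eta[j]
                val = est / denom if denom > 0 else np.nan
            elif kind == "gamma":
                i, p = key[1], pred_pos[key[2]]
                val = est * sd_x[p] / sd_eta[i] if sd_eta[i] > 0 else np.nan
            elif kind == "theta":
                v = sd_y0[key[1]] ** 2
                val = est / v if v > 0 else np.nan
            elif kind == "mu_x":
                p = pred_pos[key[1]]
                val = est / sd_x[p] if sd_x[p] > 0 else np.nan
            elif kind == "phi_x":
                i, j = key[1], key[2]
                denom = sd_x[i] * sd_x[j]
                val = est / denom if denom > 0 else np.nan
            out[st.label] = float(val)
    return out
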