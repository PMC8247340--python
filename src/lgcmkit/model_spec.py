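"""Declarative growth-model specifications and parameter bookkeeping.

A latent growth curve model (LGCM) represents repeated measures of one or
two outcomes as loadings on latent intercept and slope factors,

    y = Lambda @ eta + eps,      eta = alpha + Gamma @ (x - mu_x) + zeta,

with zeta ~ N(0, Psi), eps ~ N(0, Theta * I) (one residual variance per
outcome, homogeneous across waves) and exogenous predictors x ~ N(mu_x,
Phi_x) modeled jointly with the outcomes.  The intercept loadings are fixed
to 1 and the slope loadings to the wave times (0, 1, 2, ...), so the
intercept is the model-implied level at baseline and the slope the annual
rate of change.

A :class:`GrowthModelSpec` is a purely declarative object: for every
parameter of the model it records, per group, whether the parameter is free
(with a label; sharing one label across groups equates the parameter) or
fixed at a value.  Estimation lives in :mod:`lgcmkit.estimate`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Free",
    "Fixed",
    "GrowthModelSpec",
    "GroupParams",
    "ParameterSet",
    "base_spec",
    "model_df",
]


@dataclass(frozen=True)
class Free:
    """A freely estimated parameter, identified by a unique label.

    Two (parameter, group) slots holding the same label share a single
    free value: this is how cross-group equality constraints are encoded.
    """

    label: str


@dataclass(frozen=True)
class Fixed:
    """A parameter fixed at a known value (e.g. a zero variance)."""

    value: float


Status = Free | Fixed

# canonical parameter-matrix names, in packing order
_PARAM_ORDER = ("alpha", "psi", "gamma", "theta", "mu_x", "phi_x")


class SpecError(ValueError):
    """Raised for inconsistent or unidentifiable model specifications."""


@dataclass
class GroupParams:
    """Numeric parameter values for one group."""

    alpha: np.ndarray  # (k,) latent means
    psi: np.ndarray  # (k, k) latent residual covariance
    gamma: np.ndarray  # (k, q) paths from exogenous predictors to factors
    theta: np.ndarray  # (n_outcomes,) residual variances
    mu_x: np.ndarray  # (q,) exogenous means
    phi_x: np.ndarray  # (q, q) exogenous covariance

    def copy(self) -> "GroupParams":
        return GroupParams(
            self.alpha.copy(), self.psi.copy(), self.gamma.copy(),
            self.theta.copy(), self.mu_x.copy(), self.phi_x.copy(),
        )


@dataclass
class ParameterSet:
    """Per-group parameter values for a :class:`GrowthModelSpec`."""

    groups: dict[str, GroupParams]

    def __getitem__(self, group: str) -> GroupParams:
        return self.groups[group]


@dataclass
class GrowthModelSpec:
    name: str
    outcomes: tuple[str, ...]
    groups: tuple[str, ...]
    predictors: tuple[str, ...]
    n_waves: int = 3
    wave_times: tuple[float, ...] = (0.0, 1.0, 2.0)
    # param key -> {group label -> Free | Fixed}
    params: dict[tuple, dict[str, Status]] = field(default_factory=dict)

    # ---- structure -------------------------------------------------

    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)

    @property
    def n_factors(self) -> int:
        return 2 * self.n_outcomes

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    @property
    def n_observed(self) -> int:
        return self.n_outcomes * self.n_waves + self.n_predictors

    def factor_names(self) -> tuple[str, ...]:
        names = []
        for out in self.outcomes:
            names += [f"{out}_int", f"{out}_slope"]
        return tuple(names)

    def observed_names(self) -> tuple[str, ...]:
        cols = [f"{out}_t{k}" for out in self.outcomes for k in range(self.n_waves)]
        return tuple(cols) + tuple(self.predictors)

    def loading_matrix(self) -> np.ndarray:
        """Fixed loading matrix Lambda (n_outcome_waves x n_factors)."""
        W, k = self.n_waves, self.n_factors
        lam = np.zeros((self.n_outcomes * W, k))
        t = np.asarray(self.wave_times[:W], dtype=float)
        for m in range(self.n_outcomes):
            rows = slice(m * W, (m + 1) * W)
            lam[rows, 2 * m] = 1.0
            lam[rows, 2 * m + 1] = t
        return lam

    # ---- parameter keys --------------------------------------------

    def param_keys(self) -> list[tuple]:
        """All parameter keys in canonical packing order."""
        k, q = self.n_factors, self.n_predictors
        keys: list[tuple] = [("alpha", i) for i in range(k)]
        keys += [("psi", i, j) for i in range(k) for j in range(i, k)]
        keys += [("gamma", i, p) for i in range(k) for p in self.predictors]
        keys += [("theta", out) for out in self.outcomes]
        keys += [("mu_x", p) for p in self.predictors]
        keys += [("phi_x", i, j) for i in range(q) for j in range(i, q)]
        return keys

    def is_variance(self, key: tuple) -> bool:
        kind = key[0]
        if kind == "theta":
            return True
        if kind in ("psi", "phi_x"):
            return key[1] == key[2]
        return False

    def key_name(self, key: tuple) -> str:
        """Human-readable name for a parameter key."""
        kind = key[0]
        fac = self.factor_names()
        if kind == "alpha":
            return f"alpha[{fac[key[1]]}]"
        if kind == "psi":
            return f"psi[{fac[key[1]]},{fac[key[2]]}]"
        if kind == "gamma":
            return f"gamma[{fac[key[1]]}~{key[2]}]"
        if kind == "theta":
            return f"theta[{key[1]}]"
        if kind == "mu_x":
            return f"mu_x[{key[1]}]"
        if kind == "phi_x":
            return f"phi_x[{self.predictors[key[1]]},{self.predictors[key[2]]}]"
        raise KeyError(key)

    # ---- free-parameter bookkeeping --------------------------------

    def free_labels(self) -> list[str]:
        """Ordered unique labels of free parameters (packing order)."""
        seen: dict[str, None] = {}
        for key in self.param_keys():
            for g in self.groups:
                st = self.params[key][g]
                if isinstance(st, Free):
                    seen.setdefault(st.label, None)
        return list(seen)

    @property
    def n_free(self) -> int:
        return len(self.free_labels())

    # ---- constraint editing ----------------------------------------

    def copy(self, name: str | None = None) -> "GrowthModelSpec":
        out = copy.deepcopy(self)
        if name is not None:
            out.name = name
        return out

    def fix(self, key: tuple, value: float, groups: Iterable[str] | None = None) -> "GrowthModelSpec":
        """Return a copy with `key` fixed at `value` in the given groups."""
        out = self.copy()
        for g in groups or self.groups:
            out.params[key][g] = Fixed(float(value))
        return out

    def equate(self, key: tuple, label: str | None = None) -> "GrowthModelSpec":
        """Return a copy with `key` constrained equal across all groups."""
        out = self.copy()
        lab = label or self.key_name(key)
        for g in self.groups:
            if isinstance(out.params[key][g], Fixed):
                raise SpecError(f"cannot equate fixed parameter {key} in group {g}")
            out.params[key][g] = Free(lab)
        return out

    # ---- validation ------------------------------------------------

    def validate(self) -> None:
        keys = set(self.param_keys())
        if set(self.params) != keys:
            missing = keys - set(self.params)
            extra = set(self.params) - keys
            raise SpecError(f"parameter table mismatch: missing={missing}, extra={extra}")
        if self.n_waves < 2:
            raise SpecError("need at least two waves")
        t = self.wave_times[: self.n_waves]
        if t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise SpecError("slope loadings must increase strictly from 0")
        for key in self.param_keys():
            for g in self.groups:
                st = self.params[key][g]
                if isinstance(st, Fixed) and self.is_variance(key) and st.value < 0:
                    raise SpecError(f"fixed variance {key} in {g} is negative")
        if self.df < 0:
            raise SpecError(f"model has negative df ({self.df}): not identifiable")

    # ---- degrees of freedom ----------------------------------------

    @property
    def df(self) -> int:
        """Model degrees of freedom.

        Each group contributes p(p+3)/2 observed first and second moments
        (p means plus p(p+1)/2 covariances); the distinct free parameters
        (equated labels counted once) are subtracted.
        """
        p = self.n_observed
        return len(self.groups) * (p * (p + 3) // 2) - self.n_free

    # ---- serialization ---------------------------------------------

    def to_dict(self) -> dict:
        def enc(st: Status):
            return {"free": st.label} if isinstance(st, Free) else {"fixed": st.value}

        return {
            "name": self.name,
            "outcomes": list(self.outcomes),
            "groups": list(self.groups),
            "predictors": list(self.predictors),
            "n_waves": self.n_waves,
            "wave_times": list(self.wave_times),
            "params": [
                {"key": list(key), "status": {g: enc(st) for g, st in pg.items()}}
                for key, pg in self.params.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GrowthModelSpec":
        def dec(e: Mapping) -> Status:
            if "free" in e:
                return Free(e["free"])
            return Fixed(float(e["fixed"]))

        params: dict[tuple, dict[str, Status]] = {}
        for entry in d["params"]:
            key = tuple(entry["key"])
            params[key] = {g: dec(e) for g, e in entry["status"].items()}
        spec = cls(
            name=d["name"],
            outcomes=tuple(d["outcomes"]),
            groups=tuple(d["groups"]),
            predictors=tuple(d["predictors"]),
            n_waves=int(d["n_waves"]),
            wave_times=tuple(float(t) for t in d["wave_times"]),
            params=params,
        )
        spec.validate()
        return spec


def model_df(spec: GrowthModelSpec) -> int:
    """Degrees of freedom of a growth-model specification."""
    return spec.df


def base_spec(
    name: str,
    outcomes: Iterable[str],
    groups: Iterable[str],
    predictors: Iterable[str] = (),
    pred_targets: Mapping[str, Iterable[int]] | None = None,
    n_waves: int = 3,
    wave_times: Iterable[float] | None = None,
) -> GrowthModelSpec:
    """All-free specification with group-specific labels.

    Parameters
    ----------
    pred_targets
        Optional map predictor name -> latent factor indices it may
        predict; paths to all other factors are fixed at 0.  Default:
        every predictor predicts every factor.
    """
    outcomes = tuple(outcomes)
    groups = tuple(groups)
    predictors = tuple(predictors)
    if wave_times is None:
        wave_times = tuple(float(k) for k in range(n_waves))
    spec = GrowthModelSpec(
        name=name, outcomes=outcomes, groups=groups, predictors=predictors,
        n_waves=n_waves, wave_times=tuple(wave_times),
    )
    targets = {p: set(pred_targets[p]) if pred_targets and p in pred_targets
               else set(range(spec.n_factors)) for p in predictors}
    for key in spec.param_keys():
        per_group: dict[str, Status] = {}
        for g in groups:
            if key[0] == "gamma" and key[1] not in targets[key[2]]:
                per_group[g] = Fixed(0.0)
            else:
                per_group[g] = Free(f"{spec.key_name(key)}|{g}")
        spec.params[key] = per_group
    spec.validate()
    return spec
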