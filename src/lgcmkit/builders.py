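"""The analysis's model suite as growth-model specification factories.

Four behavioral/cognitive models (apathy and Digit Symbol, each with and
without the other's baseline score as predictor), eight regional
gray-matter-volume models (EYO and TIV as predictors of both factors),
and five carrier-only bivariate apathy-by-volume models with the four
cross-domain latent covariances free.  Each factory also produces the
constrained twin its likelihood-ratio comparison needs (slope equated
across groups, or a cross-covariance fixed at zero).

Conventions shared by all models (the unique set under which the
moment-counting rule reproduces the published degrees of freedom):
exogenous predictors are modeled jointly with the outcomes (their means,
variances and covariances are free per group), and the residual variance
is homogeneous across waves and equated across groups per outcome.
"""

from __future__ import annotations

from .cohort import CARRIER, GROUPS, NONCARRIER, REGIONS
from .model_spec import GrowthModelSpec, base_spec

__all__ = [
    "build_univariate",
    "build_regional",
    "build_bivariate",
    "equate_slopes",
    "behavioral_model",
    "catalog",
    "BIVARIATE_REGIONS",
]

BIVARIATE_REGIONS = ("frontal", "temporal", "parietal", "cingulate", "central")

INT, SLOPE = 0, 1  # factor offsets within one outcome's (intercept, slope) pair


def _equate_theta(spec: GrowthModelSpec) -> GrowthModelSpec:
    for out in spec.outcomes:
        spec = spec.equate(("theta", out))
    return spec


def build_univariate(outcome: str, predictors=("EYO",), groups=GROUPS,
                     zero_noncarrier_slope: bool = True,
                     name: str | None = None) -> GrowthModelSpec:
    """Two-group univariate growth model with predictors on both factors.

    For the behavioral/cognitive models the non-carrier slope variance and
    intercept-slope covariance are fixed at zero (the constraint the
    published fits required for proper solutions).
    """
    spec = base_spec(name or f"lgcm_{outcome}", [outcome], groups, predictors)
    spec = _equate_theta(spec)
    if zero_noncarrier_slope and NONCARRIER in groups:
        spec = spec.fix(("psi", SLOPE, SLOPE), 0.0, groups=[NONCARRIER])
        spec = spec.fix(("psi", INT, SLOPE), 0.0, groups=[NONCARRIER])
    spec.validate()
    return spec


def behavioral_model(which: int) -> GrowthModelSpec:
    """Models 1-4 of the behavioral/cognitive analysis.

    1: apathy ~ EYO; 2: apathy ~ EYO + baseline Digit Symbol;
    3: Digit Symbol ~ EYO; 4: Digit Symbol ~ EYO + baseline apathy.
    Baseline scores enter as exogenous predictors named after the wide
    table's baseline column (e.g. ``digit_symbol_t0``).
    """
    if which == 1:
        return build_univariate("apathy", name="M1_apathy")
    if which == 2:
        return build_univariate("apathy", predictors=("EYO", "digit_symbol_t0"),
                                name="M2_apathy_digit")
    if which == 3:
        return build_univariate("digit_symbol", name="M3_digit")
    if which == 4:
        return build_univariate("digit_symbol", predictors=("EYO", "apathy_t0"),
                                name="M4_digit_apathy")
    raise ValueError("behavioral model index must be 1..4")


def build_regional(region: str, groups=GROUPS) -> GrowthModelSpec:
    """Regional volume growth model: EYO and TIV predict both factors.

    The parietal model additionally fixes the non-carrier slope variance
    to zero (required for a proper converged solution).
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region '{region}'; expected one of {REGIONS}")
    spec = base_spec(f"R_{region}", [f"vol_{region}"], groups, ("EYO", "TIV"))
    spec = _equate_theta(spec)
    if region == "parietal" and NONCARRIER in groups:
        spec = spec.fix(("psi", SLOPE, SLOPE), 0.0, groups=[NONCARRIER])
    spec.validate()
    return spec


def build_bivariate(region: str) -> GrowthModelSpec:
    """Carrier-only bivariate apathy x regional-volume growth model.

    Latent factors in order: apathy intercept (0), apathy slope (1),
    volume intercept (2), volume slope (3).  EYO predicts all four
    factors; TIV only the volume factors.  The apathy intercept-slope
    covariance is fixed at zero (proper-solution constraint); the four
    cross-domain covariances are free.
    """
    if region not in BIVARIATE_REGIONS:
        raise ValueError(
            f"unknown bivariate region '{region}'; expected one of {BIVARIATE_REGIONS}")
    spec = base_spec(
        f"B_{region}", ["apathy", f"vol_{region}"], (CARRIER,), ("EYO", "TIV"),
        pred_targets={"EYO": (0, 1, 2, 3), "TIV": (2, 3)},
    )
    spec = spec.fix(("psi", 0, 1), 0.0)  # apathy intercept ~~ slope
    spec.validate()
    return spec


def fix_cross_covariance(spec: GrowthModelSpec,
                         pair: tuple[int, int] = (1, 2)) -> GrowthModelSpec:
    """Constrained twin of a bivariate model: one cross-covariance fixed 0.

    Default pair (1, 2) is apathy-slope ~~ volume-intercept, the term
    whose free estimation the bivariate comparison tests.
    """
    i, j = min(pair), max(pair)
    out = spec.fix(("psi", i, j), 0.0)
    out.name = f"{spec.name}_zerocov"
    return out


def equate_slopes(spec: GrowthModelSpec, outcome: str | None = None) -> GrowthModelSpec:
    """Constrained twin with the slope mean equated across groups."""
    outcome = outcome or spec.outcomes[0]
    m = spec.outcomes.index(outcome)
    out = spec.equate(("alpha", 2 * m + SLOPE), label=f"alpha[{outcome}_slope]|equal")
    out.name = f"{spec.name}_eqslope"
    return out


def catalog() -> dict[str, GrowthModelSpec]:
    """All named models of the analysis suite, plus constrained twins."""
    out: dict[str, GrowthModelSpec] = {}
    for i in range(1, 5):
        spec = behavioral_model(i)
        out[spec.name] = spec
        twin = equate_slopes(spec)
        out[twin.name] = twin
    for region in REGIONS:
        spec = build_regional(region)
        out[spec.name] = spec
        twin = equate_slopes(spec)
        out[twin.name] = twin
    for region in BIVARIATE_REGIONS:
        spec = build_bivariate(region)
        out[spec.name] = spec
        twin = fix_cross_covariance(spec)
        out[twin.name] = twin
    return out
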