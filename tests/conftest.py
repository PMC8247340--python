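"""Shared fixtures: small synthetic cohorts and generating-truth helpers."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import lgcmkit as lk
from lgcmkit.estimate import ParamIndex, build_model_data


def apathy_only_config(seed: int, car_slope: float = 0.511,
                       non_slope: float = 0.084, jitter: float = 0.0,
                       dropout: float = 0.2, n_car: int = 304,
                       n_non: int = 296) -> lk.CohortConfig:
    """Study-condition config reduced to the apathy outcome (M1's generator)."""
    cfg = lk.default_config(seed=seed, visit_jitter_sd=jitter,
                            dropout_per_wave=dropout,
                            n_carriers=n_car, n_noncarriers=n_non)
    ap = dataclasses.replace(
        cfg.outcomes["apathy"],
        slope_mean={"carrier": car_slope, "noncarrier": non_slope})
    return dataclasses.replace(cfg, outcomes={"apathy": ap}, cross_cov={})


def m1_wide(cfg: lk.CohortConfig) -> pd.DataFrame:
    coh = lk.apply_missingness(lk.generate_cohort(cfg), cfg)
    return lk.analysis_table(coh, ["apathy"], predictors=("EYO",))


def true_m1_vector(spec, cfg: lk.CohortConfig) -> np.ndarray:
    """Generating parameter values arranged in the spec's free-label order."""
    ap = cfg.outcomes["apathy"]
    vals = {}
    for g in ("carrier", "noncarrier"):
        cov = np.asarray(ap.latent_cov[g])
        vals[f"alpha[apathy_int]|{g}"] = ap.intercept_mean[g]
        vals[f"alpha[apathy_slope]|{g}"] = ap.slope_mean[g]
        vals[f"psi[apathy_int,apathy_int]|{g}"] = cov[0, 0]
        vals[f"psi[apathy_int,apathy_slope]|{g}"] = cov[0, 1]
        vals[f"psi[apathy_slope,apathy_slope]|{g}"] = cov[1, 1]
        vals[f"gamma[apathy_int~EYO]|{g}"] = ap.eyo_path[g][0]
        vals[f"gamma[apathy_slope~EYO]|{g}"] = ap.eyo_path[g][1]
        vals[f"mu_x[EYO]|{g}"] = cfg.eyo_mean[g]
        vals[f"phi_x[EYO,EYO]|{g}"] = cfg.eyo_sd[g] ** 2
    vals["theta[apathy]"] = ap.residual_var
    return np.array([vals[lab] for lab in spec.free_labels()])


@pytest.fixture(scope="session")
def m1_spec():
    return lk.behavioral_model(1)


@pytest.fixture(scope="session")
def small_fit():
    """One modest well-specified M1 fit with standard errors (reused widely)."""
    cfg = apathy_only_config(seed=42, n_car=150, n_non=150)
    wide = m1_wide(cfg)
    spec = lk.behavioral_model(1)
    data = build_model_data(spec, wide)
    fit = lk.fit_model(spec, data)
    return {"cfg": cfg, "wide": wide, "spec": spec, "data": data, "fit": fit}


def warm_start(target_spec, source_fit) -> np.ndarray:
    """Start vector for a nested spec taken from a fitted parent model."""
    return ParamIndex(target_spec).pack(source_fit.params)
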