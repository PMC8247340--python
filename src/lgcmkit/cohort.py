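"""Seeded synthetic two-group longitudinal cohorts.

Emulates the statistical design of a presymptomatic genetic-FTD cohort:
~304 mutation carriers and ~296 non-carrier relatives, assessed at
baseline and annually for two years, with an apathy score (CBI-R
motivation subscale, z-scored), a Digit Symbol score (z-scored), and
eight bilateral regional gray-matter volumes (z-scored), plus estimated
years to expected onset (EYO, years; negative before onset) and total
intracranial volume (TIV, ml).

Each outcome follows the latent growth curve data-generating process the
analysis assumes: per-subject latent intercept and slope drawn from a
(possibly cross-outcome) multivariate normal whose means are shifted by
centered EYO (and TIV for volumes), observed at jittered visit times with
homogeneous residual noise.  Follow-up attrition is monotone and
completely at random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "OutcomeParams",
    "CohortConfig",
    "REGIONS",
    "default_config",
    "generate_cohort",
    "apply_missingness",
    "write_cohort",
    "read_cohort",
]

CARRIER = "carrier"
NONCARRIER = "noncarrier"
GROUPS = (CARRIER, NONCARRIER)

REGIONS = ("frontal", "temporal", "parietal", "occipital",
           "insula", "cingulate", "central", "brainstem")

# gene mutation counts within the carrier group (MAPT : GRN : C9orf72)
GENE_SPLIT = {"MAPT": 54, "GRN": 142, "C9orf72": 108}


class ConfigurationError(ValueError):
    """Invalid cohort configuration (e.g. non-PSD latent covariance)."""


@dataclass
class OutcomeParams:
    """Generating parameters of one outcome's latent growth process."""

    intercept_mean: dict[str, float]
    slope_mean: dict[str, float]
    latent_cov: dict[str, np.ndarray]  # 2x2 per group, order (intercept, slope)
    eyo_path: dict[str, tuple[float, float]]  # on (intercept, slope)
    residual_var: float
    tiv_path: dict[str, tuple[float, float]] | None = None  # volumes only

    def validate(self, groups=GROUPS) -> None:
        for g in groups:
            cov = np.asarray(self.latent_cov[g], dtype=float)
            if cov.shape != (2, 2):
                raise ConfigurationError("latent covariance must be 2x2")
            if np.linalg.eigvalsh(0.5 * (cov + cov.T)).min() < -1e-10:
                raise ConfigurationError("latent covariance is not positive semidefinite")
        if self.residual_var < 0:
            raise ConfigurationError("residual variance must be non-negative")


@dataclass
class CohortConfig:
    """Design of a synthetic cohort; defaults emulate the study conditions."""

    n_carriers: int = 304
    n_noncarriers: int = 296
    n_waves: int = 3
    wave_spacing_years: float = 1.0
    eyo_mean: dict[str, float] = field(
        default_factory=lambda: {CARRIER: -14.0, NONCARRIER: -13.0})
    eyo_sd: dict[str, float] = field(
        default_factory=lambda: {CARRIER: 12.1, NONCARRIER: 14.1})
    tiv_mean: float = 1492.8
    tiv_sd: float = 142.8
    outcomes: dict[str, OutcomeParams] = field(default_factory=dict)
    # ((outcome_i, factor_i), (outcome_j, factor_j)) -> {group: covariance};
    # factor is 0 (intercept) or 1 (slope)
    cross_cov: dict[tuple, dict[str, float]] = field(default_factory=dict)
    visit_jitter_sd: float = 0.1
    dropout_per_wave: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_carriers <= 0 or self.n_noncarriers <= 0:
            raise ConfigurationError("group sizes must be positive")
        if self.n_waves < 3:
            raise ConfigurationError("need at least 3 waves")
        if not 0.0 <= self.dropout_per_wave <= 1.0:
            raise ConfigurationError("dropout probability must be in [0, 1]")
        if self.visit_jitter_sd < 0:
            raise ConfigurationError("visit jitter sd must be non-negative")
        for name, op in self.outcomes.items():
            try:
                op.validate()
            except ConfigurationError as e:
                raise ConfigurationError(f"outcome '{name}': {e}") from e
        for g in GROUPS:
            self._latent_cov_matrix(g)  # raises if the joint matrix is not PSD

    def _latent_cov_matrix(self, group: str) -> np.ndarray:
        """Joint latent covariance over all outcomes' (intercept, slope) pairs."""
        names = list(self.outcomes)
        k = 2 * len(names)
        psi = np.zeros((k, k))
        for m, name in enumerate(names):
            psi[2 * m:2 * m + 2, 2 * m:2 * m + 2] = np.asarray(
                self.outcomes[name].latent_cov[group], dtype=float)
        for (a, b), per_group in self.cross_cov.items():
            (out_i, f_i), (out_j, f_j) = a, b
            i = 2 * names.index(out_i) + f_i
            j = 2 * names.index(out_j) + f_j
            psi[i, j] = psi[j, i] = per_group.get(group, 0.0)
        if np.linalg.eigvalsh(psi).min() < -1e-8:
            raise ConfigurationError(
                f"joint latent covariance for group '{group}' is not positive semidefinite")
        return psi


def default_config(**overrides) -> CohortConfig:
    """Cohort configuration with the study-condition defaults.

    Outcome scales are z-score-like (apathy, Digit Symbol, regional
    volumes standardized to the non-carrier baseline), EYO in years, TIV
    in ml.  Carrier slope means follow the magnitudes the analysis is
    designed to detect; paths are calibrated so implied baseline SDs are
    near 1 (carrier apathy slightly wider, matching a 1.5 SD at baseline).
    """
    car, non = CARRIER, NONCARRIER
    outcomes: dict[str, OutcomeParams] = {
        "apathy": OutcomeParams(
            intercept_mean={car: 0.3, non: 0.0},
            slope_mean={car: 0.511, non: 0.084},
            latent_cov={car: np.array([[1.2, -0.05], [-0.05, 0.30]]),
                        non: np.array([[0.8, 0.0], [0.0, 0.0]])},
            eyo_path={car: (0.05, 0.010), non: (0.03, 0.0)},
            residual_var=0.25,
        ),
        "digit_symbol": OutcomeParams(
            intercept_mean={car: 0.1, non: 0.1},
            slope_mean={car: -0.077, non: 0.002},
            latent_cov={car: np.array([[0.6, -0.02], [-0.02, 0.02]]),
                        non: np.array([[0.8, 0.0], [0.0, 0.0]])},
            eyo_path={car: (-0.03, -0.008), non: (-0.028, 0.0)},
            residual_var=0.20,
        ),
    }
    # Table-2-like carrier/non-carrier annual slopes per region (z-units/year)
    region_slopes = {
        "frontal": (-0.069, -0.015), "temporal": (-0.047, -0.016),
        "parietal": (-0.025, 0.013), "occipital": (0.017, 0.014),
        "insula": (-0.020, -0.006), "cingulate": (-0.031, -0.006),
        "central": (-0.052, -0.010), "brainstem": (0.017, 0.020),
    }
    for region, (s_car, s_non) in region_slopes.items():
        non_slope_var = 0.0 if region == "parietal" else 0.006
        outcomes[f"vol_{region}"] = OutcomeParams(
            intercept_mean={car: -0.2, non: 0.0},
            slope_mean={car: s_car, non: s_non},
            latent_cov={car: np.array([[0.85, -0.005], [-0.005, 0.012]]),
                        non: np.array([[0.95, 0.0], [0.0, non_slope_var]])},
            eyo_path={car: (-0.02, -0.002), non: (-0.01, 0.0)},
            tiv_path={car: (0.002, 0.0), non: (0.002, 0.0)},
            residual_var=0.05,
        )
    # coupling between apathy change and baseline fronto-cingulate volume,
    # and between baseline apathy and cognitive decline
    cross = {
        (("apathy", 1), ("vol_frontal", 0)): {car: -0.20, non: 0.0},
        (("apathy", 1), ("vol_temporal", 0)): {car: -0.13, non: 0.0},
        (("apathy", 1), ("vol_parietal", 0)): {car: -0.12, non: 0.0},
        (("apathy", 1), ("vol_cingulate", 0)): {car: -0.14, non: 0.0},
        (("apathy", 1), ("vol_central", 0)): {car: -0.09, non: 0.0},
        (("apathy", 0), ("digit_symbol", 1)): {car: -0.05, non: 0.0},
    }
    cfg = CohortConfig(outcomes=outcomes, cross_cov=cross)
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a long-format cohort table, fully reproducible from the seed.

    One row per subject x visit, columns: subject_id, group, gene, visit,
    visit_time, EYO, TIV, and one column per outcome.  Baseline visits
    occur at exactly t=0; later visits at nominal spacing plus Gaussian
    jitter (clipped to keep visit times strictly increasing).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = list(config.outcomes)
    rows = []
    sizes = {CARRIER: config.n_carriers, NONCARRIER: config.n_noncarriers}
    for group in GROUPS:
        n = sizes[group]
        psi = config._latent_cov_matrix(group)
        # draw via eigen-decomposition so PSD-but-singular covariances work
        w, V = np.linalg.eigh(psi)
        root = V * np.sqrt(np.clip(w, 0.0, None))
        genes = _gene_labels(n, rng) if group == CARRIER else [""] * n
        eyo = rng.normal(config.eyo_mean[group], config.eyo_sd[group], size=n)
        tiv = rng.normal(config.tiv_mean, config.tiv_sd, size=n)
        zeta = rng.standard_normal((n, psi.shape[0])) @ root.T
        spacing = config.wave_spacing_years
        jitter = rng.normal(0.0, config.visit_jitter_sd,
                            size=(n, config.n_waves)) if config.visit_jitter_sd > 0 \
            else np.zeros((n, config.n_waves))
        jitter[:, 0] = 0.0  # baseline anchored at t = 0
        max_jit = 0.45 * spacing
        np.clip(jitter, -max_jit, max_jit, out=jitter)
        eps = rng.standard_normal((n, config.n_waves, len(names)))
        for i in range(n):
            eta = np.empty(2 * len(names))
            for m, name in enumerate(names):
                op = config.outcomes[name]
                mean = np.array([op.intercept_mean[group], op.slope_mean[group]])
                path = np.asarray(op.eyo_path[group], dtype=float)
                mean = mean + path * (eyo[i] - config.eyo_mean[group])
                if op.tiv_path is not None:
                    tpath = np.asarray(op.tiv_path[group], dtype=float)
                    mean = mean + tpath * (tiv[i] - config.tiv_mean)
                eta[2 * m:2 * m + 2] = mean + zeta[i, 2 * m:2 * m + 2]
            for k in range(config.n_waves):
                t = k * spacing + jitter[i, k]
                row = {
                    "subject_id": f"{group[:3]}{i:04d}",
                    "group": group,
                    "gene": genes[i],
                    "visit": k,
                    "visit_time": t,
                    "EYO": eyo[i],
                    "TIV": tiv[i],
                }
                for m, name in enumerate(names):
                    op = config.outcomes[name]
                    noise = np.sqrt(op.residual_var) * eps[i, k, m]
                    row[name] = eta[2 * m] + eta[2 * m + 1] * t + noise
                rows.append(row)
    return pd.DataFrame(rows)


def _gene_labels(n: int, rng: np.random.Generator) -> list[str]:
    """Gene labels at fixed 54:142:108 proportions (no distinct effects)."""
    total = sum(GENE_SPLIT.values())
    counts = {g: int(round(n * c / total)) for g, c in GENE_SPLIT.items()}
    # fix rounding drift on the largest stratum
    drift = n - sum(counts.values())
    counts["GRN"] += drift
    labels = [g for g, c in counts.items() for _ in range(c)]
    rng.shuffle(labels)
    return labels


def apply_missingness(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Monotone completely-at-random dropout.

    Each subject independently drops out before each follow-up wave with
    probability ``config.dropout_per_wave``; once a wave is missed all
    later waves are missing.  The baseline row is never removed.  Seeded
    from ``config.seed`` (offset so visit draws and dropout draws differ).
    """
    p = config.dropout_per_wave
    if p == 0:
        return cohort.copy()
    if p >= 1:
        warnings.warn("dropout probability >= 1: all follow-up waves removed",
                      UserWarning)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    keep = np.ones(len(cohort), dtype=bool)
    for _, idx in cohort.groupby("subject_id", sort=False).groups.items():
        sub = cohort.loc[idx].sort_values("visit")
        alive = True
        for row_label, visit in zip(sub.index, sub["visit"]):
            if visit == 0:
                continue
            if alive and rng.random() < p:
                alive = False
            if not alive:
                keep[cohort.index.get_loc(row_label)] = False
    return cohort.loc[keep].reset_index(drop=True)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the long-format table as CSV (missing values as empty cells)."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "gene" in df.columns:
        df["gene"] = df["gene"].fillna("")
    return df


def write_config(config: CohortConfig, path) -> None:
    d = {
        "n_carriers": config.n_carriers, "n_noncarriers": config.n_noncarriers,
        "n_waves": config.n_waves, "wave_spacing_years": config.wave_spacing_years,
        "eyo_mean": dict(config.eyo_mean), "eyo_sd": dict(config.eyo_sd),
        "tiv_mean": config.tiv_mean, "tiv_sd": config.tiv_sd,
        "visit_jitter_sd": config.visit_jitter_sd,
        "dropout_per_wave": config.dropout_per_wave, "seed": config.seed,
        "outcomes": {
            name: {
                "intercept_mean": dict(op.intercept_mean),
                "slope_mean": dict(op.slope_mean),
                "latent_cov": {g: np.asarray(c).tolist()
                               for g, c in op.latent_cov.items()},
                "eyo_path": {g: list(v) for g, v in op.eyo_path.items()},
                "tiv_path": ({g: list(v) for g, v in op.tiv_path.items()}
                             if op.tiv_path else None),
                "residual_var": op.residual_var,
            } for name, op in config.outcomes.items()
        },
        "cross_cov": [
            {"i": list(a), "j": list(b), "value": dict(per_group)}
            for (a, b), per_group in config.cross_cov.items()
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_config(path) -> CohortConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    outcomes = {
        name: OutcomeParams(
            intercept_mean=o["intercept_mean"],
            slope_mean=o["slope_mean"],
            latent_cov={g: np.asarray(c, dtype=float)
                        for g, c in o["latent_cov"].items()},
            eyo_path={g: tuple(v) for g, v in o["eyo_path"].items()},
            tiv_path=({g: tuple(v) for g, v in o["tiv_path"].items()}
                      if o.get("tiv_path") else None),
            residual_var=float(o["residual_var"]),
        ) for name, o in d["outcomes"].items()
    }
    cross = {}
    for entry in d.get("cross_cov", []):
        key = ((entry["i"][0], int(entry["i"][1])), (entry["j"][0], int(entry["j"][1])))
        cross[key] = entry["value"]
    cfg = CohortConfig(
        n_carriers=d["n_carriers"], n_noncarriers=d["n_noncarriers"],
        n_waves=d["n_waves"], wave_spacing_years=d["wave_spacing_years"],
        eyo_mean=d["eyo_mean"], eyo_sd=d["eyo_sd"],
        tiv_mean=d["tiv_mean"], tiv_sd=d["tiv_sd"],
        outcomes=outcomes, cross_cov=cross,
        visit_jitter_sd=d["visit_jitter_sd"],
        dropout_per_wave=d["dropout_per_wave"], seed=d["seed"],
    )
    cfg.validate()
    return cfg
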