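"""Analysis-ready transforms: z-scoring to the non-carrier baseline,
annualization of irregular visit times, laterality index, and lobar
aggregation of atlas regions.

All scores entering the growth models are expressed as z-scores relative
to the non-carrier (gene-negative) group at baseline, which quantifies
relative severity without disclosing genetic status.  Follow-up values
observed at slightly irregular intervals are recomputed at nominal years
1 and 2 so the slope loadings (0, 1, 2) describe annual change.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceStats",
    "reference_stats",
    "zscore_to_reference",
    "annualize",
    "laterality_index",
    "lobar_aggregate",
    "load_atlas",
    "analysis_table",
]


class PreprocessError(ValueError):
    pass


@dataclass
class ReferenceStats:
    """Per-variable mean and SD from non-carrier baseline rows (ddof=1)."""

    stats: dict[str, tuple[float, float]]  # variable -> (mean, sd)

    def __contains__(self, var: str) -> bool:
        return var in self.stats

    def mean(self, var: str) -> float:
        return self.stats[var][0]

    def sd(self, var: str) -> float:
        return self.stats[var][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v, m, s) for v, (m, s) in self.stats.items()],
            columns=["variable", "mean", "sd"])


def _baseline_noncarrier(cohort: pd.DataFrame) -> pd.DataFrame:
    if "visit" in cohort.columns:
        base = cohort["visit"] == 0
    else:
        base = np.abs(cohort["visit_time"]) < 0.5
    return cohort.loc[(cohort["group"] == "noncarrier") & base]


def reference_stats(cohort: pd.DataFrame, variables) -> ReferenceStats:
    """Mean/SD per variable over non-carrier baseline rows.

    Altering carrier rows can never change the result; SD uses the n-1
    denominator.  Raises when a variable has fewer than two non-missing
    baseline values or zero variance.
    """
    ref = _baseline_noncarrier(cohort)
    stats: dict[str, tuple[float, float]] = {}
    for var in variables:
        vals = ref[var].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise PreprocessError(
                f"variable '{var}': fewer than 2 non-carrier baseline values")
        sd = float(vals.std(ddof=1))
        if sd <= 0:
            raise PreprocessError(f"variable '{var}' has zero baseline variance")
        stats[var] = (float(vals.mean()), sd)
    return ReferenceStats(stats=stats)


def zscore_to_reference(cohort: pd.DataFrame, stats: ReferenceStats) -> pd.DataFrame:
    """(value - reference mean) / reference SD, all rows and visits.

    Missing stays missing; variables absent from the reference raise.
    """
    out = cohort.copy()
    for var in stats.stats:
        if var not in out.columns:
            raise PreprocessError(f"variable '{var}' not in cohort table")
        out[var] = (out[var] - stats.mean(var)) / stats.sd(var)
    return out


def inverse_zscore(cohort: pd.DataFrame, stats: ReferenceStats) -> pd.DataFrame:
    out = cohort.copy()
    for var in stats.stats:
        out[var] = out[var] * stats.sd(var) + stats.mean(var)
    return out


def annualize(visit_times, values, nominal_years, slack: float = 0.5) -> np.ndarray:
    """Recompute a subject's trajectory at nominal (integer) years.

    The baseline value passes through unchanged.  A nominal year k
    bracketed by two observed visits is linearly interpolated; a nominal
    year just past the final visit (within `slack` years, covering
    jittered final waves) is linearly rescaled from baseline through the
    nearest visit j as value0 + (value_j - value0) * k / t_j; nominal
    years further beyond the last observation are missing.  The rule is
    exact for any trajectory linear in time.
    """
    t = np.asarray(visit_times, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = ~(np.isnan(t) | np.isnan(v))
    t, v = t[ok], v[ok]
    order = np.argsort(t)
    t, v = t[order], v[order]
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise PreprocessError("duplicate visit times")
    out = np.full(len(nominal_years), np.nan)
    if len(t) == 0:
        return out
    for i, k in enumerate(nominal_years):
        if k == 0 or np.isclose(k, t[0]):
            out[i] = v[0]
        elif k < t[0]:
            continue  # before first observation: undefined
        elif k <= t[-1]:
            out[i] = np.interp(k, t, v)
        elif k - t[-1] <= slack and t[-1] > 0:
            out[i] = v[0] + (v[-1] - v[0]) * (k / t[-1])
    return out


def laterality_index(left_volume: float, right_volume: float) -> float:
    """|L - R| / (L + R): scale-free asymmetry in [0, 1], symmetric in L, R."""
    if left_volume < 0 or right_volume < 0:
        raise PreprocessError("volumes must be non-negative")
    total = left_volume + right_volume
    if total <= 0:
        raise PreprocessError("total volume must be positive")
    return abs(left_volume - right_volume) / total


def lobar_aggregate(regional_volumes: dict, atlas_map: dict) -> dict:
    """Sum member-region volumes into bilateral lobar composites.

    Every region must have a lobe assignment; left/right variants of one
    structure simply both map to the same composite.
    """
    unassigned = [r for r in regional_volumes if r not in atlas_map]
    if unassigned:
        raise PreprocessError(f"regions with no lobe assignment: {sorted(unassigned)}")
    out: dict[str, float] = {}
    for region, vol in regional_volumes.items():
        if vol < 0:
            raise PreprocessError(f"negative volume for region '{region}'")
        lobe = atlas_map[region]
        out[lobe] = out.get(lobe, 0.0) + float(vol)
    return out


def load_atlas(path=None) -> dict:
    """Region -> lobe map from a two-column TSV; default ships with the
    package (Desikan-Killiany cortical labels plus subcortical structures,
    grouped into the eight bilateral composites)."""
    if path is None:
        src = resources.files("lgcmkit.data").joinpath("dk_atlas.tsv")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        region, lobe = line.split("\t")
        out[region] = lobe
    return out


# ----------------------------------------------------------------------
# wide analysis tables
# ----------------------------------------------------------------------

def analysis_table(cohort: pd.DataFrame, outcomes, n_waves: int = 3,
                   predictors=("EYO",)) -> pd.DataFrame:
    """One row per subject: annualized outcome waves plus baseline predictors.

    Each outcome contributes columns ``{outcome}_t0 .. _t{n_waves-1}``
    (annualized at nominal years); predictors are taken from the baseline
    row.  A predictor of the form ``{outcome}_t0`` (a baseline score used
    as an exogenous regressor) is produced automatically.
    """
    records = []
    nominal = list(range(n_waves))
    for sid, sub in cohort.groupby("subject_id", sort=False):
        sub = sub.sort_values("visit_time")
        base = sub.iloc[0]
        rec: dict = {"subject_id": sid, "group": base["group"]}
        if "gene" in sub.columns:
            rec["gene"] = base["gene"]
        for pred in predictors:
            if pred in sub.columns:
                rec[pred] = base[pred]
        for out in outcomes:
            vals = annualize(sub["visit_time"].to_numpy(),
                             sub[out].to_numpy(), nominal)
            for k in nominal:
                rec[f"{out}_t{k}"] = vals[k]
        records.append(rec)
    wide = pd.DataFrame(records)
    # baseline-score predictors like "apathy_t0" already exist as columns
    return wide
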