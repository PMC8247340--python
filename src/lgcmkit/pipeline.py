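"""End-to-end workflow: preprocess a cohort table, fit the model suite,
and emit regional/bivariate report tables with FDR correction.

The behavioral stage fits the four apathy/cognition models and their
slope-equated twins; the regional stage fits eight univariate volume
models with Benjamini-Hochberg correction across the eight slope-equality
tests and (separately) across the eight carrier-slope tests; the
bivariate stage fits the five carrier-only apathy-by-volume models and
tests the apathy-slope ~ volume-intercept covariance against zero.
Improper solutions (variances on the zero bound) are flagged and refit
with the offending variance fixed at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .builders import (BIVARIATE_REGIONS, behavioral_model, build_bivariate,
                       build_regional, equate_slopes, fix_cross_covariance)
from .cohort import CARRIER, NONCARRIER, REGIONS
from .estimate import FitOptions, FitResult, build_model_data, fit_model, refit_constrained
from .fit_indices import ComparisonResult, FitIndices, fit_statistics, lrt_compare
from .model_spec import GrowthModelSpec
from .preprocess import analysis_table, reference_stats, zscore_to_reference

__all__ = [
    "fdr_adjust",
    "preprocess_cohort",
    "run_behavioral",
    "run_regional",
    "run_bivariate",
    "run_pipeline",
    "write_reports",
]


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def preprocess_cohort(cohort: pd.DataFrame, variables=None) -> pd.DataFrame:
    """z-score outcomes to the non-carrier baseline (EYO/TIV left raw)."""
    if variables is None:
        variables = [c for c in cohort.columns
                     if c in ("apathy", "digit_symbol") or c.startswith("vol_")]
    stats = reference_stats(cohort, variables)
    return zscore_to_reference(cohort, stats)


@dataclass
class ModelReport:
    """Fit, indices, and (optionally) the slope-equality comparison."""

    name: str
    fit: FitResult
    indices: FitIndices
    comparison: ComparisonResult | None = None
    improper_handled: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"name": self.name, "converged": self.fit.converged,
             "n_free": self.fit.n_free, "improper_handled": self.improper_handled}
        d.update(self.indices.to_dict())
        if self.comparison is not None:
            d["comparison"] = self.comparison.to_dict()
        d["parameters"] = self.fit.summary_frame().to_dict(orient="records")
        return d


def _fit_proper(spec: GrowthModelSpec, data, options=None) -> tuple[FitResult, list[str]]:
    """Fit, then apply the flag-then-constrain remedy for improper solutions."""
    fit = fit_model(spec, data, options)
    if not fit.converged:
        raise RuntimeError(f"model '{spec.name}' did not converge")
    handled = list(fit.improper)
    if handled:
        fit = refit_constrained(fit, data, options)
        if not fit.converged:
            raise RuntimeError(f"model '{spec.name}' did not converge after constraining")
    return fit, handled


def _slope_row(fit: FitResult, outcome: str, group: str) -> dict:
    """Estimate/SE/z/p of a group's slope mean from the robust SEs."""
    spec = fit.spec
    m = spec.outcomes.index(outcome)
    st = spec.params[("alpha", 2 * m + 1)][group]
    est = fit.estimate(st.label)
    se = fit.robust_se_of(st.label)
    z = est / se if se > 0 else np.nan
    return {"estimate": est, "se": se, "z": z,
            "p": 2.0 * float(norm.sf(abs(z))) if np.isfinite(z) else np.nan}


def _compare_slopes(fit: FitResult, data, options
                    ) -> tuple[ComparisonResult, FitResult]:
    # build the twin from the fitted spec so any improper-solution fixes carry over
    twin = equate_slopes(fit.spec)
    twin_fit, _ = _fit_proper(twin, data, options)
    return lrt_compare(fit, twin_fit), twin_fit


def run_behavioral(cohort: pd.DataFrame, options: FitOptions | None = None
                   ) -> dict[str, ModelReport]:
    """Fit models 1-4 and their slope-equality comparisons.

    Expects a preprocessed (z-scored) long-format cohort with apathy and
    digit_symbol columns; annualization happens here.
    """
    wide = analysis_table(cohort, ["apathy", "digit_symbol"],
                          predictors=("EYO", "TIV"))
    reports: dict[str, ModelReport] = {}
    for i in range(1, 5):
        spec = behavioral_model(i)
        data = build_model_data(spec, wide)
        fit, handled = _fit_proper(spec, data, options)
        comparison, _ = _compare_slopes(fit, data, options)
        reports[spec.name] = ModelReport(
            name=spec.name, fit=fit, indices=fit_statistics(fit, data),
            comparison=comparison, improper_handled=handled)
    return reports


def run_regional(cohort: pd.DataFrame, options: FitOptions | None = None,
                 regions=REGIONS) -> pd.DataFrame:
    """Eight univariate volume models; returns a Table-2-shaped frame.

    Benjamini-Hochberg correction is applied across the eight
    slope-equality Delta-chi-square p-values and, as a separate family,
    across the eight carrier-slope p-values.
    """
    wide = analysis_table(cohort, [f"vol_{r}" for r in regions],
                          predictors=("EYO", "TIV"))
    rows = []
    for region in regions:
        spec = build_regional(region)
        data = build_model_data(spec, wide)
        fit, handled = _fit_proper(spec, data, options)
        idx = fit_statistics(fit, data)
        comparison, _ = _compare_slopes(fit, data, options)
        row = {"region": region, "chisq": idx.chisq, "df": idx.df,
               "chisq_per_df": idx.chisq_per_df, "rmsea": idx.rmsea,
               "cfi": idx.cfi, "srmr": idx.srmr, "aic": idx.aic,
               "improper_handled": ";".join(handled)}
        for group, tag in ((NONCARRIER, "noncar"), (CARRIER, "carrier")):
            s = _slope_row(fit, f"vol_{region}", group)
            row.update({f"slope_{tag}_{k}": v for k, v in s.items()})
        row["delta_chisq"] = comparison.delta_chisq
        row["delta_df"] = comparison.delta_df
        row["delta_chisq_p"] = comparison.pvalue
        rows.append(row)
    table = pd.DataFrame(rows)
    table["delta_chisq_p_fdr"] = fdr_adjust(table["delta_chisq_p"])
    table["slope_carrier_p_fdr"] = fdr_adjust(table["slope_carrier_p"])
    return table


def run_bivariate(cohort: pd.DataFrame, options: FitOptions | None = None,
                  regions=BIVARIATE_REGIONS) -> pd.DataFrame:
    """Five carrier-only bivariate models; returns a Table-3-shaped frame.

    Reports the four cross-domain covariance rows (estimate, robust SE,
    z, p) and the likelihood-ratio test of fixing the apathy-slope ~
    volume-intercept covariance to zero.
    """
    cross_rows = {
        "int_ap_int_br": (0, 2),
        "slope_ap_int_br": (1, 2),
        "slope_br_int_ap": (0, 3),
        "slope_ap_slope_br": (1, 3),
    }
    carriers = cohort[cohort["group"] == CARRIER]
    rows = []
    for region in regions:
        spec = build_bivariate(region)
        wide = analysis_table(carriers, ["apathy", f"vol_{region}"],
                              predictors=("EYO", "TIV"))
        data = build_model_data(spec, wide)
        fit, handled = _fit_proper(spec, data, options)
        idx = fit_statistics(fit, data)
        twin = fix_cross_covariance(spec)
        twin_fit, _ = _fit_proper(twin, data, options)
        comparison = lrt_compare(fit, twin_fit)
        row = {"region": region, "chisq": idx.chisq, "df": idx.df,
               "chisq_per_df": idx.chisq_per_df, "rmsea": idx.rmsea,
               "cfi": idx.cfi, "srmr": idx.srmr, "aic": idx.aic,
               "improper_handled": ";".join(handled)}
        for tag, (i, j) in cross_rows.items():
            key = ("psi", min(i, j), max(i, j))
            st = spec.params[key][CARRIER]
            if hasattr(st, "label") and st.label in fit.labels:
                est = fit.estimate(st.label)
                se = fit.robust_se_of(st.label)
                z = est / se if se > 0 else np.nan
                p = 2.0 * float(norm.sf(abs(z))) if np.isfinite(z) else np.nan
            else:  # fixed away by an improper-solution refit
                est, se, z, p = 0.0, np.nan, np.nan, np.nan
            row.update({f"{tag}_est": est, f"{tag}_se": se,
                        f"{tag}_z": z, f"{tag}_p": p})
        row["delta_chisq"] = comparison.delta_chisq
        row["delta_df"] = comparison.delta_df
        row["delta_chisq_p"] = comparison.pvalue
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cohort: pd.DataFrame, out_dir=None,
                 options: FitOptions | None = None) -> dict:
    """Preprocess, then run the behavioral, regional and bivariate stages.

    Deterministic: the same cohort table always produces byte-identical
    reports.  Returns the in-memory results; writes TSV/JSON reports when
    `out_dir` is given.
    """
    z = preprocess_cohort(cohort)
    results = {
        "behavioral": run_behavioral(z, options),
        "regional": run_regional(z, options),
        "bivariate": run_bivariate(z, options),
    }
    if out_dir is not None:
        write_reports(results, out_dir)
    return results


def write_reports(results: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    behavioral = {name: rep.to_dict() for name, rep in results["behavioral"].items()}
    with open(out / "behavioral.json", "w") as fh:
        json.dump(behavioral, fh, indent=2, default=float)
    results["regional"].to_csv(out / "regional.tsv", sep="\t", index=False,
                               float_format="%.6g")
    results["bivariate"].to_csv(out / "bivariate.tsv", sep="\t", index=False,
                                float_format="%.6g")
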