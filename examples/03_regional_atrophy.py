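"""Regional gray-matter volume models with FDR-corrected group tests.

Fits a univariate growth model per bilateral region (EYO and total
intracranial volume predicting both factors) plus its slope-equated
twin, then applies Benjamini-Hochberg correction across the region-level
slope-equality tests — the Table-2-style report of the workflow.
"""

import lgcmkit as lk

cfg = lk.default_config(seed=11)
cohort = lk.apply_missingness(lk.generate_cohort(cfg), cfg)
cohort = lk.preprocess_cohort(cohort)

table = lk.run_regional(cohort)
cols = ["region", "chisq", "df", "slope_carrier_estimate", "slope_carrier_se",
        "delta_chisq", "delta_chisq_p", "delta_chisq_p_fdr"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
# negative carrier slopes are annual z-units of volume loss; regions whose
# FDR-adjusted slope-equality p stays below 0.05 show atrophy beyond the
# non-carrier ageing rate (frontal, temporal, cingulate and central
# structures under the default generating design; occipital and
# brainstem are generated null and should not survive correction)
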