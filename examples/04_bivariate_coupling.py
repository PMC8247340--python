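"""Bivariate growth model: does low baseline volume predict apathy change?

In carriers only, apathy and one regional volume grow in parallel; the
four cross-domain latent covariances link their intercepts and slopes.
The key parameter is cov(apathy slope, volume intercept): a negative
value means carriers with less gray matter at baseline accumulate apathy
faster.  The likelihood-ratio test compares the free model against a
twin with that covariance fixed to zero.
"""

import lgcmkit as lk

cfg = lk.default_config(seed=23)
cohort = lk.apply_missingness(lk.generate_cohort(cfg), cfg)
cohort = lk.preprocess_cohort(cohort)

table = lk.run_bivariate(cohort, regions=("frontal", "cingulate"))
for _, row in table.iterrows():
    print(f"{row['region']}: chi2[{row['df']}] = {row['chisq']:.2f}")
    print(f"  cov(apathy slope, volume intercept) = "
          f"{row['slope_ap_int_br_est']:.3f} "
          f"(SE {row['slope_ap_int_br_se']:.3f}, p = {row['slope_ap_int_br_p']:.3g})")
    print(f"  zero-coupling test: delta-chi2 = {row['delta_chisq']:.2f}, "
          f"p = {row['delta_chisq_p']:.3g}")
# both regions are generated with negative coupling (-0.20 frontal,
# -0.14 cingulate): the covariance estimates come out negative and the
# constrained model is rejected, i.e. baseline fronto-cingulate volume
# carries information about subsequent apathy progression
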