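"""Generate a synthetic presymptomatic-FTD-style cohort and inspect it.

Builds the default two-group design (304 mutation carriers, 296
non-carrier relatives; baseline plus two annual follow-ups with jittered
visit times and 20% per-wave monotone dropout) and prints the retention
and baseline summaries a data manager would check first.
"""

import lgcmkit as lk

cfg = lk.default_config(seed=7)
cohort = lk.apply_missingness(lk.generate_cohort(cfg), cfg)

n_subjects = cohort["subject_id"].nunique()
print(f"subjects: {n_subjects}, rows: {len(cohort)}")
for k in range(cfg.n_waves):
    frac = (cohort["visit"] == k).sum() / n_subjects
    print(f"  wave {k}: retention {frac:.2f}")
# retention at wave k is (1 - dropout)^k in expectation: 1.00, 0.80, 0.64

baseline = cohort[cohort["visit"] == 0]
for group, sub in baseline.groupby("group"):
    print(f"{group}: n={len(sub)}, "
          f"EYO {sub['EYO'].mean():.1f} ± {sub['EYO'].std():.1f} y, "
          f"apathy z {sub['apathy'].mean():.2f} ± {sub['apathy'].std():.2f}")
# carriers sit ~14 years before expected onset with slightly higher and
# more variable apathy than non-carriers, mirroring the design the
# generator emulates

lk.write_cohort(cohort, "cohort.csv")
print("wrote cohort.csv (long format, one row per subject x visit)")
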