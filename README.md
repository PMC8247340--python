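# lgcmkit

Multigroup **latent growth curve modeling** (LGCM) with full-information
maximum likelihood, built for short longitudinal cohorts of the kind
collected in presymptomatic genetic frontotemporal dementia (FTD)
studies: two groups (mutation carriers vs. non-carrier relatives), three
annual waves, irregular visit intervals, and monotone dropout.  The
package answers questions such as *does apathy progress faster in
carriers than in non-carriers?*, *does baseline apathy predict
subsequent cognitive decline?*, and *does baseline fronto-cingulate gray
matter volume predict apathy progression?* — all without access to
restricted study data, via a seeded synthetic cohort generator with the
same statistical structure.

## The model

Repeated measures $y_{t}$ ($t = 0, 1, 2$ years) load on a latent
intercept $\eta_0$ (level at baseline) and linear slope $\eta_1$ (annual
change):

$$y_t = \eta_0 + t\,\eta_1 + \varepsilon_t, \qquad
\eta = \alpha + \Gamma (x - \mu_x) + \zeta,$$

with $\zeta \sim N(0, \Psi)$, $\varepsilon_t \sim N(0, \theta)$
(homogeneous across waves), and exogenous predictors $x$ (estimated
years to onset EYO; total intracranial volume TIV; a baseline score)
modeled jointly as $x \sim N(\mu_x, \Phi_x)$.  All parameters may be
free, fixed, or equated across groups.  Estimation is full-information
maximum likelihood over missing-data patterns (FIML), standard errors
are sandwich ($A^{-1} B A^{-1}$) estimates from casewise scores, and
model adequacy is judged by $\chi^2$, $\chi^2/df$, RMSEA (with 90% CI),
CFI, SRMR and AIC.  Group differences (e.g. in the slope mean) are
tested by likelihood-ratio $\Delta\chi^2$ against an equality-constrained
twin model, with Benjamini–Hochberg FDR correction across regional model
families.

The shipped model catalog covers: four behavioral models (apathy and
Digit Symbol trajectories, each with and without the other's baseline
score as predictor), eight regional gray-matter-volume models (EYO + TIV
as predictors; the parietal model fixes the non-carrier slope variance
at zero), and five carrier-only bivariate apathy-by-volume models whose
four cross-domain latent covariances quantify coupling between baseline
level and change across domains.

## Worked example

```python
import lgcmkit as lk
from lgcmkit.estimate import build_model_data

cfg = lk.default_config(seed=7)                       # 304 carriers / 296 non-carriers
cohort = lk.apply_missingness(lk.generate_cohort(cfg), cfg)
cohort = lk.preprocess_cohort(cohort)                 # z-score to non-carrier baseline

wide = lk.analysis_table(cohort, ["apathy"], predictors=("EYO",))
spec = lk.behavioral_model(1)                         # apathy ~ EYO, two groups
data = build_model_data(spec, wide)
fit = lk.fit_model(spec, data)
print(lk.fit_statistics(fit, data).to_dict())
cmp = lk.lrt_compare(fit, lk.fit_model(lk.equate_slopes(spec), data))
```

Running `examples/02_apathy_growth_model.py` (which does exactly this)
prints:

```
chi2[11] = 11.19, p = 0.427, chi2/df = 1.02
RMSEA = 0.008 [0.000-0.061], CFI = 1.00, SRMR = 0.020
carrier slope: est = 0.414, SE = 0.039, z = 10.62
noncarrier slope: est = 0.069, SE = 0.022, z = 3.19
slope equality: delta-chi2 = 55.79, delta-df = 1, p = 8.1e-14
```

Reading: the linear growth model is consistent with the data
($\chi^2/df \approx 1$, RMSEA well under 0.05); carriers' apathy rises by
0.41 z-units per year (on the z-scored scale) while non-carriers are
near-flat; and the equality-constrained model is decisively rejected, so
the groups differ in their rate of change.  The other scripts in
`examples/` walk through cohort simulation, the eight-region atrophy
table with FDR correction, and the bivariate apathy-volume coupling
models.

A thin CLI mirrors the workflow:

```bash
lgcmkit simulate --seed 3 --out cohort.csv
lgcmkit preprocess --in cohort.csv --out cohort_z.csv
lgcmkit models list
lgcmkit pipeline run --cohort cohort.csv --out reports/
```

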