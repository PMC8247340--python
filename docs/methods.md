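# Methods

## Model and estimation

`lgcmkit` fits linear latent growth curve models (LGCMs) to short
longitudinal panels.  For each outcome, the three annualized measures
load on a latent intercept (fixed loadings 1, 1, 1) and a latent slope
(fixed loadings 0, 1, 2 — the wave times in years), so the intercept is
the model-implied level at baseline and the slope the annual rate of
change.  Exogenous predictors (EYO, TIV, a baseline score) are modeled
*jointly* with the outcomes: their means and covariances are free
parameters per group, and their effect on the latent factors enters as
paths on the mean-centered predictor.  This convention — rather than
conditioning on the predictors — was chosen because it is the unique
one under which the moment-counting rule

&nbsp;&nbsp;df = Σ_groups p(p+3)/2 − (# distinct free parameters)

reproduces the degrees of freedom of the entire model catalog (11 and 13
for the behavioral models, 11 regional, 12 parietal, 18 bivariate) from
a single rule, and because it lets FIML use subjects whose outcomes are
missing but whose predictors are observed.

The residual variance is homogeneous across waves and equated across
groups (one θ per outcome), again the unique convention consistent with
the catalog's dfs; it is an overridable property of the specification
objects, not of the engine.

**Likelihood.** Subjects are grouped by missing-data pattern; each
pattern contributes the multivariate-normal density of its observed
sub-vector under the corresponding sub-mean/sub-covariance of the
implied moments (full-information maximum likelihood).  With complete
data this reduces exactly to the joint MVN likelihood, which the test
suite asserts.  A non-positive-definite implied covariance returns −∞
(surfaced to the optimizer as a large finite penalty), not an exception.

**Optimization.** L-BFGS-B on a diagonally preconditioned scale: each
free parameter is divided by its natural magnitude (e.g. sd_i·sd_j for a
covariance), derived from moment-based starting values.  Starting values
are deterministic: wave-mean OLS for the latent means, a fixed split of
the baseline variance for the latent/residual variances, observed
moments for the predictors.  Free variances are box-constrained at zero
and optimized on the direct (not log) scale: a log-parametrized variance
cannot converge when the MLE sits on the zero boundary, whereas the
bounded direct scale reaches the bound cleanly and makes the
improper-solution flag exact.  Because a line search that strays into
the infeasible penalty region can corrupt the quasi-Newton curvature
memory and stall the optimizer far from the optimum, the engine restarts
L-BFGS-B with fresh memory (with a small deterministic nudge if truly
stalled) until the projected gradient is below 1e−5·|loglik|; ten
jittered restarts agree in log-likelihood to well below 1e−6 on the test
problems.

**Improper solutions.** A free variance estimated at its zero bound
(below 1e−6) is flagged; the pipeline's remedy is flag-then-constrain:
refit with that variance fixed at zero (at most three rounds).  The
parietal regional model ships with the non-carrier slope variance fixed
at zero a priori, and the behavioral models fix the non-carrier slope
variance and intercept–slope covariance at zero, mirroring the
constraints the published fits required.

**Standard errors.** Naive SEs are the square root of the diagonal of
the inverse observed information (central-difference Hessian, step
eps^{1/3}·max(1,|θ|)).  Robust SEs are the sandwich A⁻¹BA⁻¹ with A the
observed information and B the sum of casewise score outer products
(central differences of the per-subject log-likelihood).  z-values and
reported p-values use the robust SEs.  At an active variance bound the
differentiation center is shifted just inside the feasible region; a
singular A falls back to the pseudo-inverse with a warning flag.
Note a structural limit: the sandwich needs finite fourth moments to be
consistent for second-moment parameters, so the heavy-tail validation
uses t₅ (excess kurtosis 6) rather than heavier residuals.

**Fit statistics.** The model χ² is 2(llₛₐₜ − llₘ), where the saturated
log-likelihood is maximized by EM over missing-data patterns (E-step:
conditional expectations of missing entries and their second moments;
M-step: closed-form mean/covariance update; the likelihood sequence is
asserted non-decreasing at every iteration and equals the closed-form
MLE on complete data).  The CFI baseline is the independence model,
whose FIML likelihood factorizes over variables and is available in
closed form.  RMSEA uses the multigroup form √G·√(max(χ²−df,0)/(df·N))
with the 90% CI from inverting the noncentral-χ² CDF in the
noncentrality parameter; CFI = 1 − max(χ²−df,0)/max(χ²_b−df_b, χ²−df, 0);
SRMR is the root mean squared standardized residual of means and
covariances (saturated EM moments standing in for sample moments under
missingness), averaged over groups; AIC = −2ll + 2k.  Published RMSEA
values for this class of models are not exactly recoverable from printed
N, χ², df under any standard variant, so the formula above is simply
documented, not tuned.  χ² differences for nested models use the plain
(unscaled) likelihood-ratio statistic with the central χ² tail; printed
Δχ² p-values in the source tables are reproduced exactly by this choice,
so robustness enters only through the sandwich SEs.

**Standardization.** Paths are scaled by implied source SD over implied
target SD (latent variances taken as diag(ΓΦΓᵀ+Ψ)); covariances become
correlations; standardized estimates are invariant to rescaling of the
raw variables, which the suite asserts.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes: 304
presymptomatic carriers and 296 non-carrier relatives, baseline plus two
annual waves, EYO drawn per group (−14.0 ± 12.1 and −13.0 ± 14.1 years),
TIV 1492.8 ± 142.8 ml, carrier gene labels at fixed 54:142:108
(MAPT:GRN:C9orf72) proportions with no distinct effects.  Each outcome
follows exactly the LGCM the engine fits: latent (intercept, slope)
drawn from a per-group bivariate normal with mean shifted by centered
EYO (and TIV for volumes), observed at visit times with Gaussian jitter
(sd 0.1 years; baseline anchored at 0) plus homogeneous residual noise.
Cross-outcome couplings (apathy slope with regional-volume intercepts;
apathy intercept with Digit Symbol slope) enter as off-diagonal blocks
of one joint latent covariance, validated positive semidefinite.

Default generating values are calibrated so the implied baseline SDs and
group contrasts match the magnitudes the analysis is designed to detect:
carrier apathy slope 0.511 vs 0.084 z/year, Digit Symbol −0.077 vs
0.002, regional slopes between −0.069 (frontal) and +0.020 (brainstem),
frontal and cingulate coupling covariances −0.20 and −0.14.  EYO paths
are set so the EYO contribution to baseline variance is modest (≈0.2–0.4
z² over a 12-year SD); the published per-year path magnitudes could not
be used directly because their scale is not recoverable from the source
tables.  Dropout is monotone and completely at random at 0.2 per
follow-up wave (a placeholder; real attrition rates are not published) —
FIML is consistent under the broader MAR class, and MCAR is the simplest
testable case.  EYO is generated independently of the latent residuals,
so its paths carry the entire EYO–outcome association.

What the generator does *not* emulate: floor effects and skew of the
CBI-R apathy subscale (real carer-rated scores are zero-inflated;
residuals here are Gaussian), correlations among regional volumes
(independent by default, configurable via cross-covariances), site and
scanner effects, informative dropout, and symptomatic conversion.
Passing recovery tests therefore certify the estimator under the model's
own assumptions, not robustness to these real-data features — except for
the heavy-tail robust-SE check, which deliberately violates normality.

## Preprocessing

Scores are z-scored to the mean/SD (n−1 denominator) of non-carrier
baseline rows, the reference that quantifies severity without disclosing
genetic status.  Annualization maps each subject's irregular visit times
onto nominal years: baseline passes through; a bracketed nominal year is
linearly interpolated; a nominal year within half a wave-spacing beyond
the final visit is proportionally rescaled from baseline through that
visit (value₀ + (value_j − value₀)·k/t_j); later years are missing.  The
rule is exact for any trajectory linear in time, which is the property
tests assert; the half-spacing cutoff resolves the tension between
"rescale from the nearest visit" and "beyond the last observation is
missing" in favour of keeping jittered final waves.  The laterality
index is |L−R|/(L+R) — total volume read as L+R of the structure so the
index is scale-free in [0,1] — and the Desikan-Killiany region→composite
map ships as an editable TSV rather than code, since only the composite
names, not the assignments, are fixed.

## Testing strategy and problem sizes

Every operation is checked against an independent route: FIML vs the
explicit complete-data MVN density; the EM saturated fit vs the
closed-form MLE and vs a brute-force Nelder-Mead over all moment
parameters (n=20, 30% missingness, agreement to 1e−4); balanced-design
slope means vs per-subject OLS slopes; the full engine vs statsmodels
MixedLM (random intercept + slope, ML) on complete balanced data; BH
adjustment vs a brute-force min-over-j evaluation.  Monte-Carlo suites
run at study scale (n=600, 3 waves, 20% monotone dropout, jitter 0 so
the wave times are exact): 200 replicates for parameter recovery (every
generating parameter within 3 Monte-Carlo SEs) and robust-CI coverage
(bounded in [0.92, 0.98]), 300 replicates for the type-I error of the
slope-equality Δχ² test (bounded in [0.03, 0.07]).  Replicate counts for
the power, null-FDR and coupling recovery properties are smaller (10–30)
since those effects are large by design.  The acceptance script uses 100
recovery and 200 type-I replicates.

## Known limitations

General SEM path diagrams, categorical indicators, nonlinear (latent
basis or quadratic) growth, Satorra–Bentler scaled test statistics, and
more than three waves in the shipped catalog are out of scope.  The
gene-specific grouping argument exists but ships untested against
published values (the subgroup sizes do not support stable LGCM fits).
Numerical gradients make single fits O(0.1–1 s) at study scale; an
analytic-gradient backend would be the natural next optimization.
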