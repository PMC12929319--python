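# Methods

`hsuvmix` models the longitudinal evolution of EQ-5D-3L health-state
utility values (HSUVs) after kidney transplantation (KT) and predicts
patient trajectories from baseline clinical covariates.  This note
documents the statistical models, the numerical choices behind them,
the synthetic cohort generator used for validation, and the known
limitations.

## Outcome scale and transforms

A French EQ-5D-3L tariff maps each 5-digit questionnaire profile to a
utility u in [u_min, u_max] = [−0.53, 1.00].  The tariff coefficients
are not shipped; `valueset.py` accepts any additive value set (per-level
decrements per dimension plus optional any-problem / any-level-3
constants) from a documented YAML schema, and can enumerate the full
243-profile grid of attainable values.

Two of the four model families work on the *decrement* scale,

    y = (u_max − u) / (u_max − u_min)  ∈ [0, 1],

the rescaled shortfall from full health.  Because a beta density has no
mass at 0 or 1, observed decrements are compressed strictly inside the
unit interval with y\* = [y(N−1) + 0.5]/N, where N is the number of
observations entering that likelihood.  For the two-part model the
conditional part uses N = number of *positive* decrements: compressing
before the split would destroy the exact zeros that define the
zero-inflation state, making it vacuous.  Predictions on the decrement
scale are mapped back with u = u_max − y(u_max − u_min).

Follow-up time t (years since KT) enters all models through a
piecewise-linear basis with a knot at 1 year (configurable):
t_pre = min(t, 1), t_post = max(t − 1, 0).  The two slopes capture the
fast recovery during the first post-operative year and the slow
long-term decline; the basis is continuous at the knot, so predicted
trajectories are too.

## Model families

All families share the fixed-effect structure
η = β₀ + Σ β_k x_k + β_pre t_pre + β_post t_post with uncentred
covariates (a centring option exists; it only moves the intercept).
Male sex is coded 1.

* **Linear mixed model (lmm).**  u_ij = η_ij + b₀i + b₁i t_pre,ij + ε_ij
  with independent random intercept b₀ ~ N(0, σ₀²), random first-year
  slope b₁ ~ N(0, σ₁²) (correlation optionally estimated) and residual
  ε ~ N(0, σ²).  The marginal likelihood is multivariate normal per
  patient and is evaluated in closed form; β is profiled out by
  generalised least squares, so the optimiser works on 2–4 variance
  parameters only.
* **Mixed beta regression (beta).**  y\*_ij ~ Beta(μφ, (1−μ)φ) with
  logit μ_ij = η_ij + b₀i + b₁i t_pre,ij and precision φ.  The same
  random-effect structure as the lmm is kept for symmetry.
* **Mixed two-part beta (twopart_beta).**  A zero-inflated beta model:
  a mixed logistic regression for P(y = 0) (utility exactly at the
  ceiling) with its own independent random intercept, plus a mixed beta
  regression for the positive decrements.  Because the parts share
  neither parameters nor random effects, the likelihood factorises and
  the parts are maximised separately — this halves the wall time and
  changes nothing in the estimates.
* **Mixed ALDVMM (aldvmm).**  K normal components on the utility scale
  with shared covariate and time effects, per-class intercepts α_c and
  SDs σ_c, class probabilities π, and one shared patient random
  intercept added to every component mean.  A latent value above the
  ceiling threshold Ψ₁ is observed as u_max, below u_min as u_min, and
  interior values as themselves, which yields probability masses at
  both bounds.  Ψ₁ defaults to 0.9 (or the largest attainable value-set
  utility below u_max when a value set is supplied).  K ≥ 3 is accepted
  but flagged experimental: at typical cohort sizes the extra classes
  rarely converge.

Random-effect structures follow the variance components the reference
tables actually report (random intercept + first-year slope for the
linear and conditional-beta parts; a single independent intercept for
the zero part; one shared intercept for the mixture) with independence
as the default — no correlations are reported, and estimating one is
left as an option.

## Estimation

Non-Gaussian marginal likelihoods integrate the 1- or 2-dimensional
random effects per patient by **adaptive Gauss–Hermite quadrature**
(9 nodes per dimension by default, tensor grid in 2-D).  Per patient
the integrand's mode is located by a damped Newton search, vectorised
across all patients, using analytic first and second derivatives of the
conditional log-densities with respect to the linear predictor (the
mixture family differentiates its score numerically).  The grid is
centred at the mode and scaled by the local curvature; for a Gaussian
integrand the rule is then exact at any node count, and on beta-family
test fixtures the log-likelihood moves by < 1e−7 between 9 and 21
nodes.

Two numerical choices deserve a note:

* **Deterministic mode search.**  The conditional densities are not
  log-concave everywhere, so the per-patient integrand can be
  multimodal in b.  Newton is therefore started from the best point of
  a deterministic prior-scaled scan (7 Gauss–Hermite abscissae in 1-D,
  5×5 in 2-D, plus b = 0) rather than from a cached previous solution —
  caching was observed to make the likelihood history-dependent, which
  derails quasi-Newton optimisation.  The 2-D Newton curvature is kept
  positive definite by a closed-form eigenvalue floor.
* **Bounded mixture SDs.**  ALDVMM component SDs are parameterised as
  σ_c = 0.01 + exp(x).  The floor (1% of the utility scale, far below
  any plausible residual SD) removes the unbounded-likelihood spikes
  that normal mixtures develop when a component collapses onto a data
  atom.

Optimisation is L-BFGS-B on an unconstrained parameterisation (log SDs,
log φ, logit-simplex for π), with up to three polish restarts (a fresh
Hessian approximation often finishes what a stalled line search left
behind).  A fit whose relative projected-gradient norm exceeds 1e−2 is
reported as a ConvergenceError carrying best-so-far diagnostics.  The
mixture runs a seeded multi-start (10 by default), keeps the best
converged start, and resolves label switching by sorting classes by
intercept.

Complete-case handling mirrors the reference analysis: rows missing any
model covariate are dropped and counted at observation and patient
level.

## Covariate selection and class choice

For each family: (1) a univariate screen fits base (intercept + two
slopes + random effects) versus base + candidate and keeps candidates
with likelihood-ratio p < 0.20 (χ², df = added coefficients — 1 for
binary/continuous, 2 when the two BMI indicators enter as a pair);
(2) forward selection repeatedly adds the remaining screened candidate
with the smallest LRT p while p < 0.05, with deterministic tie-breaks
by candidate order.  Candidates never alter the random structure.  The
ALDVMM class count is the BIC argmin over K ∈ {1, 2}; a non-convergent
K is reported in the table and excluded.

## Evaluation

Precision: RMSE, MAE and the prediction range, computed on
fixed-effect-only predictions (zero random effects) — the scale at
which a new patient would be predicted.  Calibration: observations are
split into 10 groups by deciles of the predictions (stable ranks, group
sizes differ by ≤ 1); the 10 observed means are regressed on the 10
predicted means by unweighted OLS.  Perfect calibration is intercept 0,
slope 1.  Aberrant deciles are flagged by externally studentized
residual |r| > 2.5 or Cook's distance > 0.5 on the 10-point regression
(the named diagnostics with conventional cut-offs; the reference
analysis states no thresholds), at most two are excluded, and the line
is refit once.  A numerically perfect line skips the outlier rule
(studentized residuals are 0/0 noise there).  Evaluation is
within-sample by default, matching the reference analysis; a held-out
split is available but off by default.

## Synthetic cohort generator

The study cohort (2,787 adult recipients, 5,679 questionnaires) is not
deposited, so every pipeline stage is validated on synthetic cohorts
emulating its published structure:

* **Covariates** drawn independently at the published moments: age
  ~ N(50.0, 14.2²) truncated to [18, 90]; 63.0% men; BMI categories
  4.3/83.7/12.0%; diabetes 13.6%; cardiovascular disease 34.5%;
  neoplasia 11.5%; hypertension 86.6%; first transplant 85.3%;
  relapsing nephropathy 28.1%; dialysis years ~ Gamma moment-matched to
  mean 2.5, SD 3.3; donor age ~ N(51.6, 15.7²) truncated to [0, 100].
  Comorbidity correlations are not published, so independence is the
  default.
* **Visit process**: questionnaire counts 51.3% / 22.7% / 25.9% for
  1 / 2 / ≥3, the ≥3 tail geometric with ratio 0.6 truncated at 10;
  completion times i.i.d. truncated-exponential with mean 4 years on
  [0.08, 29.5], sorted per patient.  The exponential mean is a
  calibration to three published facts (≈20% of questionnaires inside
  year 1, maximum 29.5 years, median latest completion 5 years), not a
  claim about the real visit process; everything is configurable.
* **Outcomes** under any family at configured true parameters; defaults
  are the published linear-mixed-model and two-part coefficient tables.
  The beta precision φ is not published; the generator default is 5 and
  recovery tests always compare against the generator's own configured
  value.  Linear-model outputs are *not* clamped to [−0.53, 1] by
  default so that maximum likelihood stays unbiased in recovery studies
  (a clamp option exists for realism); two-part draws emit exact u = 1
  in the zero state; an optional discretiser snaps interior values to a
  value-set grid.

Under these defaults the generator reproduces the published cohort
summaries (mean HSUV ≈ 0.82 under the linear parameterisation, ≈ 40%
ceiling share under the two-part parameterisation) without further
tuning.

What passing recovery tests show — and what they do not: the synthetic
cohorts have independent covariates, a non-informative visit process
and no dropout, whereas the real cohort surely has correlated
comorbidities and follow-up that ends at graft failure or death.
Recovery results therefore validate the estimation machinery, not the
clinical transportability of any fitted coefficients.

## Validation harness and problem sizes

The acceptance-style checks simulate at the published point estimates
and refit across seeds:

* Linear mixed model: 5 seeds × 2,787 patients; median estimates of the
  sex, diabetes and dialysis effects, both time slopes, and the three
  variance components are required to fall inside the published 95%
  confidence intervals.  Each refit takes well under a second thanks to
  the profiled closed-form likelihood.
* Two-part beta: 5 seeds × 1,000 patients (the package's chosen
  simulation size for this family; the quadrature refits dominate the
  harness cost and the published intervals remain the pass bands);
  median zero-part sex and conditional diabetes coefficients must fall
  inside the published intervals.
* Exact oracles: the quadrature path reproduces the closed-form
  Gaussian marginal likelihood to < 1e−6; a 1-class ALDVMM with
  inactive censoring reproduces the random-intercept linear fit to
  1e−3; the statsmodels MixedLM maximum-likelihood fit is matched to
  1e−4 on a 150-patient fixture.
* Selection calibration: a null covariate passes the p < 0.20 screen at
  an empirical rate of 0.20 ± 0.05 over 200 replicates of 300 patients;
  a diabetes-sized effect passes in ≥ 95% of 20 replicates at 2,787
  patients.
* Smaller structural checks (forward-selection recovery, BIC class
  choice) run at 250–400 patients.

## Limitations

* The ALDVMM omits covariates in the class-membership probabilities and
  treats K ≥ 3 as experimental, matching the scope of the reference
  analysis.
* No dropout or informative-missingness model: utilities are simulated
  and fitted as if follow-up ended non-informatively.
* Marginal predictions for the nonlinear families average over the
  random-effect distribution by quadrature; conditional-on-zero-effects
  predictions (the default, and what the precision metrics use) are not
  population means for those families.
* Within-sample evaluation overstates out-of-sample performance; the
  held-out option exists for that reason.
* The exact functional form of the French tariff (interaction terms) is
  not claimed; the value-set schema covers additive tariffs with
  any-problem / any-level-3 constants.
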