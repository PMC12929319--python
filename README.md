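# hsuvmix

Longitudinal mixed-effects modelling of EQ-5D-3L health-state utility
values (HSUVs) after kidney transplantation.

Cost-effectiveness analyses need quality-adjusted life-years (QALYs),
and QALYs need utilities — but clinical studies and registries rarely
collect preference-based quality-of-life measures.  `hsuvmix` is for
health economists and biostatisticians who want to *predict* a kidney
transplant recipient's EQ-5D-3L utility trajectory from routinely
collected baseline data (age, sex, BMI, comorbidities, dialysis
history), and for methodologists comparing model families for bounded,
ceiling-inflated longitudinal outcomes.

## Models

Utilities u lie in [u_min, u_max] = [−0.53, 1.00] (French 3L tariff
bounds), with a large probability mass at the ceiling u = 1.  Follow-up
time enters through a piecewise-linear basis split at 1 year post-KT,
t_pre = min(t, 1), t_post = max(t − 1, 0), and every model carries the
fixed effects

    η_ij = β₀ + Σ_k β_k x_ik + β_pre t_pre,ij + β_post t_post,ij.

Four families are estimated by maximum marginal likelihood, with
patient-level random effects integrated out in closed form (Gaussian)
or by adaptive Gauss–Hermite quadrature:

1. **Linear mixed model** — u_ij = η_ij + b₀i + b₁i t_pre,ij + ε_ij,
   independent random intercept and first-year slope.
2. **Mixed beta regression** — on the compressed decrement
   y\* ∈ (0, 1), y = (u_max − u)/(u_max − u_min):
   y\*_ij ~ Beta(μ_ij φ, (1 − μ_ij) φ), logit μ_ij = η_ij + b₀i + b₁i t_pre,ij.
3. **Mixed two-part (zero-inflated) beta** — a mixed logistic model for
   P(u = u_max) with its own random intercept, times a mixed beta
   model for the positive decrements.
4. **Mixed ALDVMM** — a K-component mixture of normals on the utility
   scale with censoring thresholds that create probability masses at
   both bounds, shared covariate effects, and a shared random
   intercept.

Around the models: EQ-5D-3L profile scoring under any additive value
set, the decrement/compression transforms, likelihood-ratio covariate
selection (univariate screen at p < 0.20, forward selection at
p < 0.05), BIC choice of the mixture class count, RMSE/MAE and decile
calibration (β₀, β₁ of observed-on-predicted decile means, with
studentized-residual/Cook outlier handling), trajectory prediction with
trapezoidal QALYs, and a synthetic cohort generator that emulates the
published cohort structure.  See `docs/methods.md` for the full
statistical account.

## Worked example

Simulate a 500-patient cohort under the linear-model defaults, fit the
linear mixed model, and predict two patients' trajectories:

```bash
hsuvmix simulate -o cohort.csv --n-patients 500 --seed 42
# wrote 1139 rows for 500 patients to cohort.csv

hsuvmix fit -i cohort.csv -o results --family lmm --seed 1
# lmm: loglik=133.0 BIC=-181.6 RMSE=0.341 MAE=0.267 calibration (b0, b1)=(0.180, 0.797)

printf "age,sex,bmi_gt30,diabetes,cardiovascular,dialysis_years\n50,1,0,0,0,0\n62,0,0,1,1,4\n" > profiles.csv
hsuvmix predict -m results/model_lmm.json -i profiles.csv -o trajectories.csv \
    --times 0,0.5,1,2,5,10 --qaly
head -7 trajectories.csv
# row,time,predicted_hsuv,qaly_increment
# 0,0.0,0.8576213572202966,
# 0,0.5,0.8715308270725484,0.43228804607321125
# 0,1.0,0.8854402969248002,0.4392427809993371
# 0,2.0,0.8794350197019992,0.8824376583133997
# 0,5.0,0.8614191880335963,2.6112813116033933
# 0,10.0,0.8313928019195915,4.23202997488297
```

Reading the output: the healthy 50-year-old man (row 0) is predicted at
utility 0.858 at transplantation, rising to 0.885 at 1 year (the
first-year slope) and drifting slowly down to 0.831 by 10 years; the
`qaly_increment` column is the trapezoidal integral of the trajectory
over each interval, so his predicted QALY gain over years 5–10 is 4.23.
The 62-year-old woman with diabetes, cardiovascular disease and four
dialysis years starts much lower (0.575).  The fit line reports
within-sample precision (RMSE/MAE on fixed-effect predictions) and the
calibration intercept/slope of the ten decile means — (0, 1) would be
perfect; at 500 patients the slope estimate is still noisy.

`results/` also contains `model_lmm.json` (the full serialised fit:
coefficients, variance components, diagnostics), `metrics.csv` and
`calibration_lmm.csv`.  The same pipeline runs with
`--family beta|twopart_beta|aldvmm`, with `--select` for the
likelihood-ratio covariate selection, and library users can do all of
this in Python via `hsuvmix.fit_model`, `predict_utility`,
`calibration_by_deciles`, etc.

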