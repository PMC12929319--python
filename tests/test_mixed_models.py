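"""Model families: likelihoods, oracles, fitting and prediction."""

import numpy as np
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from hsuvmix import (
    FittedModel,
    ModelSpec,
    SyntheticCohortConfig,
    fit_model,
    generate_cohort,
    information_criteria,
    linear_predictor,
    loglik_marginal_quadrature,
    obs_loglik_conditional,
    predict_utility,
)
from hsuvmix.errors import DataError
from hsuvmix.synthetic import LMM_TRUE_PARAMS, TWOPART_TRUE_PARAMS
from hsuvmix.transforms import time_basis

TABLE_COEFS = dict(LMM_TRUE_PARAMS["beta"])


# ---------------------------------------------------------------- predictor


def test_linear_predictor_reference_patient_arithmetic():
    # reference woman aged 50, no comorbidity, at transplantation
    woman50 = {"age": 50, "sex": 0, "bmi_gt30": 0, "diabetes": 0,
               "cardiovascular": 0, "dialysis_years": 0}
    assert linear_predictor(
        {k: 0 for k in woman50}, 0.0, TABLE_COEFS
    ) == pytest.approx(0.881)
    assert linear_predictor(woman50, 0.0, TABLE_COEFS) == pytest.approx(0.781)
    man50 = {**woman50, "sex": 1}
    assert linear_predictor(man50, 0.0, TABLE_COEFS) == pytest.approx(0.855)


def test_linear_predictor_missing_covariate_raises():
    with pytest.raises(DataError):
        linear_predictor({"age": 50}, 0.0, TABLE_COEFS)


# ------------------------------------------------- conditional log-densities


def test_conditional_density_lmm_is_normal():
    spec = ModelSpec(family="lmm")
    ll = obs_loglik_conditional(0.8, 0.8, 0.0, spec, {"sd_resid": 0.1})
    assert ll == pytest.approx(np.log(1 / (0.1 * np.sqrt(2 * np.pi))))


def test_conditional_density_beta_uniform_case():
    # mu = 0.5, phi = 2 gives Beta(1, 1): log-density 0 everywhere inside
    spec = ModelSpec(family="beta", u_min=0.0, u_max=1.0)
    for u in (0.2, 0.5, 0.9):
        ll = obs_loglik_conditional(u, 0.0, 0.0, spec, {"phi": 2.0, "n_compress": 1000})
        assert ll == pytest.approx(0.0, abs=1e-9)


def test_conditional_density_twopart_degenerate_zero_inflation():
    spec = ModelSpec(family="twopart_beta")
    theta = {"phi": 5.0, "n_compress": 100, "eta_zero": 40.0}
    at_ceiling = obs_loglik_conditional(1.0, 0.0, 0.0, spec, theta)
    below = obs_loglik_conditional(0.8, 0.0, 0.0, spec, theta)
    assert at_ceiling == pytest.approx(0.0, abs=1e-12)
    assert below < -30


def test_conditional_density_aldvmm_ceiling_mass_half():
    # component mean exactly at the ceiling threshold: half the latent
    # mass censors upward
    spec = ModelSpec(family="aldvmm", psi1=0.9)
    theta = {"class_intercepts": [0.9], "class_sigmas": [0.1], "class_probs": [1.0]}
    ll = obs_loglik_conditional(1.0, 0.0, 0.0, spec, theta)
    assert ll == pytest.approx(np.log(0.5))


# -------------------------------------------------------- marginal likelihood


def test_quadrature_matches_closed_form_gaussian(small_lmm_cohort):
    cohort, _ = small_lmm_cohort
    sub = cohort[cohort.patient_id <= 20]
    spec = ModelSpec(family="lmm", covariates=("sex",))
    fm = fit_model(sub, spec)
    theta = {"beta": fm.coefficients, **fm.variance_components}
    ll_quad = loglik_marginal_quadrature(sub, spec, theta)
    assert abs(ll_quad - fm.loglik) < 1e-6


def test_quadrature_node_convergence(beta_cohort):
    cohort, params = beta_cohort
    spec = ModelSpec(family="beta", covariates=("sex",))
    lls = {
        n: loglik_marginal_quadrature(cohort, spec, params, n_nodes=n)
        for n in (9, 15, 21)
    }
    assert abs(lls[15] - lls[9]) < 1e-4
    assert abs(lls[21] - lls[15]) < 1e-4


def test_quadrature_point_mass_limit(beta_cohort):
    # vanishing random-effect SDs: marginal = conditional at b = 0
    cohort, params = beta_cohort
    spec = ModelSpec(family="beta", covariates=("sex",))
    theta = {**params, "sd_intercept": 1e-8, "sd_slope": 1e-8}
    ll = loglik_marginal_quadrature(cohort, spec, theta)

    from hsuvmix.data import build_design, prepare_cohort
    from hsuvmix.transforms import TransformSpec, compress, rescale_to_decrement
    from hsuvmix.families import BetaObs

    coh = prepare_cohort(cohort, ("sex",))
    X, names = build_design(coh.df, ("sex",))
    beta = np.array([params["beta"][n] for n in names])
    tspec = TransformSpec(-0.53, 1.0, coh.n_obs)
    y_star = compress(rescale_to_decrement(coh.df["hsuv"].to_numpy(), tspec), tspec)
    ll_b0 = BetaObs(y_star, params["phi"]).logpdf(X @ beta).sum()
    assert ll == pytest.approx(ll_b0, abs=1e-5)


def test_gaussian_scaling_identity():
    # data fixed at the conditional mean: doubling sigma costs n log 2
    from hsuvmix.families import GaussianObs

    u = np.full(7, 0.8)
    ll1 = GaussianObs(u, 0.1).logpdf(np.full(7, 0.8)).sum()
    ll2 = GaussianObs(u, 0.2).logpdf(np.full(7, 0.8)).sum()
    assert ll1 - ll2 == pytest.approx(7 * np.log(2))


def test_aldvmm_likelihood_invariant_to_component_permutation(small_lmm_cohort):
    cohort, _ = small_lmm_cohort
    spec = ModelSpec(family="aldvmm", covariates=("sex",), psi1=0.93, random_slope=False)
    theta = {
        "beta": {"sex": 0.05, "t_pre": 0.03, "t_post": -0.005},
        "class_intercepts": [0.3, 0.6],
        "class_sigmas": [0.1, 0.08],
        "class_probs": [0.4, 0.6],
        "sd_intercept": 0.08,
        "psi1": 0.93,
    }
    permuted = {
        **theta,
        "class_intercepts": [0.6, 0.3],
        "class_sigmas": [0.08, 0.1],
        "class_probs": [0.6, 0.4],
    }
    ll = loglik_marginal_quadrature(cohort, spec, theta)
    ll_p = loglik_marginal_quadrature(cohort, spec, permuted)
    assert ll == pytest.approx(ll_p, abs=1e-9)


# ------------------------------------------------------------------- fitting


def test_lmm_fit_matches_mixedlm_oracle(small_lmm_cohort):
    cohort, _ = small_lmm_cohort
    spec = ModelSpec(family="lmm", covariates=("sex",))
    fm = fit_model(cohort, spec)

    df = cohort.copy()
    t_pre, t_post = time_basis(df["time"].to_numpy())
    df["t_pre"], df["t_post"] = t_pre, t_post
    md = smf.mixedlm(
        "hsuv ~ sex + t_pre + t_post", df, groups=df["patient_id"], re_formula="~t_pre"
    )
    free = sm.regression.mixed_linear_model.MixedLMParams.from_components(
        fe_params=np.ones(4), cov_re=np.eye(2)
    )
    oracle = md.fit(reml=False, free=free, method="lbfgs")
    assert fm.loglik == pytest.approx(oracle.llf, abs=1e-4)
    assert fm.coefficients["sex"] == pytest.approx(oracle.params["sex"], abs=1e-4)
    assert fm.coefficients["intercept"] == pytest.approx(
        oracle.params["Intercept"], abs=1e-4
    )
    assert fm.variance_components["sd_resid"] == pytest.approx(
        np.sqrt(oracle.scale), abs=1e-3
    )


def test_aldvmm_one_class_equals_lmm_without_censoring(small_lmm_cohort):
    # psi1 above every observation and no boundary mass: the mixture
    # density is a plain normal, so the fits must coincide
    cohort, _ = small_lmm_cohort
    spec_a = ModelSpec(
        family="aldvmm", covariates=("sex",), n_classes=1, psi1=0.995, random_slope=False
    )
    spec_l = ModelSpec(family="lmm", covariates=("sex",), random_slope=False)
    fa = fit_model(cohort, spec_a, seed=1)
    fl = fit_model(cohort, spec_l)
    assert fa.class_intercepts[0] == pytest.approx(fl.coefficients["intercept"], abs=1e-3)
    assert fa.coefficients["sex"] == pytest.approx(fl.coefficients["sex"], abs=1e-3)
    assert fa.variance_components["class_sigmas"][0] == pytest.approx(
        fl.variance_components["sd_resid"], abs=1e-3
    )
    assert fa.variance_components["sd_intercept"] == pytest.approx(
        fl.variance_components["sd_intercept"], abs=1e-3
    )


def test_twopart_without_zeros_reproduces_beta_fit(beta_cohort):
    # beta-family data has no exact ceiling values, so the two-part
    # conditional part must match the one-part beta fit
    cohort, _ = beta_cohort
    assert not (cohort["hsuv"] >= 1.0).any()
    spec_b = ModelSpec(family="beta", covariates=("sex",))
    spec_t = ModelSpec(family="twopart_beta", covariates=("sex",))
    fb = fit_model(cohort, spec_b)
    ft = fit_model(cohort, spec_t)
    for name, value in fb.coefficients.items():
        assert ft.coefficients[name] == pytest.approx(value, abs=2e-3)
    assert ft.variance_components["phi"] == pytest.approx(
        fb.variance_components["phi"], rel=1e-2
    )
    assert ft.extras["n_zero"] == 0


def test_fit_counts_missing_covariate_exclusions(small_lmm_cohort):
    cohort, _ = small_lmm_cohort
    df = cohort.copy()
    victims = df["patient_id"].isin([3, 7])
    df.loc[victims, "sex"] = np.nan
    fm = fit_model(df, ModelSpec(family="lmm", covariates=("sex",)))
    assert fm.n_excluded_patients == 2
    assert fm.n_excluded_obs == int(victims.sum())
    assert fm.n_patients == cohort["patient_id"].nunique() - 2


# --------------------------------------------------------------- information


def test_information_criteria_identities(small_lmm_cohort):
    cohort, _ = small_lmm_cohort
    fm = fit_model(cohort, ModelSpec(family="lmm", covariates=("sex",)))
    aic, bic = information_criteria(fm)
    assert aic == pytest.approx(-2 * fm.loglik + 2 * fm.n_params)
    assert bic == pytest.approx(-2 * fm.loglik + fm.n_params * np.log(fm.n_obs))

    # nested model: BIC difference = -2 dLL + log n
    fm2 = fit_model(cohort, ModelSpec(family="lmm", covariates=("sex", "diabetes")))
    d_ll = fm2.loglik - fm.loglik
    assert fm2.bic - fm.bic == pytest.approx(-2 * d_ll + np.log(fm.n_obs), abs=1e-8)
    assert fm2.loglik >= fm.loglik - 1e-8  # larger model cannot fit worse


# ----------------------------------------------------------------- prediction


def _table3_model():
    return FittedModel(
        spec=ModelSpec(family="lmm"),
        coefficients=dict(LMM_TRUE_PARAMS["beta"]),
        variance_components={
            "sd_intercept": 0.231, "sd_slope": 0.213, "corr": None, "sd_resid": 0.122,
        },
        loglik=0.0, n_params=12, n_obs=5679, n_patients=2787,
    )


def _table4_model():
    return FittedModel(
        spec=ModelSpec(family="twopart_beta"),
        coefficients=dict(TWOPART_TRUE_PARAMS["beta"]),
        zero_coefficients=dict(TWOPART_TRUE_PARAMS["gamma"]),
        variance_components={
            "sd_intercept": 0.766, "sd_slope": 0.872, "corr": None,
            "phi": 5.0, "sd_zero_intercept": 2.112,
        },
        loglik=0.0, n_params=22, n_obs=5679, n_patients=2787,
    )


MAN50 = {"age": 50, "sex": 1, "bmi_gt30": 0, "diabetes": 0,
         "cardiovascular": 0, "dialysis_years": 0}


def test_lmm_prediction_reference_patient():
    assert predict_utility(_table3_model(), MAN50, 0.0) == pytest.approx(0.855)


def test_twopart_prediction_arithmetic():
    # P0 = 0.5 and mu = 0.4 give decrement 0.2, i.e. u = 1 - 0.2 * 1.53
    fm = FittedModel(
        spec=ModelSpec(family="twopart_beta", covariates=()),
        coefficients={"intercept": float(np.log(0.4 / 0.6)), "t_pre": 0.0, "t_post": 0.0},
        zero_coefficients={"intercept": 0.0, "t_pre": 0.0, "t_post": 0.0},
        variance_components={"sd_intercept": 0.5, "sd_slope": 0.5, "corr": None,
                             "phi": 5.0, "sd_zero_intercept": 1.0},
        loglik=0.0, n_params=8, n_obs=100, n_patients=50,
    )
    assert predict_utility(fm, {}, 0.0) == pytest.approx(1 - 0.2 * 1.53, abs=1e-9)


@pytest.mark.parametrize("mode", ["conditional_b0", "marginal"])
def test_predictions_continuous_at_the_knot(mode):
    for fm in (_table3_model(), _table4_model()):
        lo = predict_utility(fm, MAN50, 1.0 - 1e-9, mode=mode)
        hi = predict_utility(fm, MAN50, 1.0 + 1e-9, mode=mode)
        assert lo == pytest.approx(hi, abs=1e-6)


@pytest.mark.parametrize("mode", ["conditional_b0", "marginal"])
def test_predictions_within_utility_bounds(mode):
    times = np.linspace(0, 30, 40)
    profiles = [
        MAN50,
        {"age": 85, "sex": 0, "bmi_gt30": 1, "diabetes": 1, "cardiovascular": 1,
         "dialysis_years": 20},
        {"age": 18, "sex": 1, "bmi_gt30": 0, "diabetes": 0, "cardiovascular": 0,
         "dialysis_years": 0},
    ]
    for fm in (_table3_model(), _table4_model()):
        for x in profiles:
            u = np.atleast_1d(predict_utility(fm, x, times, mode=mode))
            assert np.all(u >= -0.53 - 1e-12)
            assert np.all(u <= 1.0 + 1e-12)


def test_aldvmm_prediction_bounds_and_class_ordering(small_lmm_cohort):
    cohort, _ = small_lmm_cohort
    spec = ModelSpec(family="aldvmm", covariates=("sex",), n_classes=2, psi1=0.93,
                     random_slope=False, n_starts=2)
    fm = fit_model(cohort, spec, seed=4)
    assert fm.class_intercepts == sorted(fm.class_intercepts)
    u = predict_utility(fm, {"sex": 1}, np.array([0.0, 1.0, 5.0]))
    assert np.all((u >= -0.53) & (u <= 1.0))


def test_fitted_model_json_round_trip(tmp_path, small_lmm_cohort):
    cohort, _ = small_lmm_cohort
    fm = fit_model(cohort, ModelSpec(family="lmm", covariates=("sex",)))
    path = tmp_path / "model.json"
    fm.save(path)
    fm2 = FittedModel.load(path)
    assert fm2.coefficients == pytest.approx(fm.coefficients)
    assert fm2.spec == fm.spec
    t = np.array([0.0, 2.5])
    assert predict_utility(fm2, {"sex": 1}, t) == pytest.approx(
        predict_utility(fm, {"sex": 1}, t)
    )
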