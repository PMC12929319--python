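"""The four longitudinal model families and their maximum-likelihood fits.

Candidate families for bounded health-state utilities u in
[u_min, u_max] observed repeatedly per patient:

``lmm``
    Linear mixed model on the raw utility scale; random intercept and
    (by default) a random slope on the pre-knot time basis; closed-form
    marginal normal likelihood (see :mod:`hsuvmix.lmm`).
``beta``
    Mixed beta regression of the compressed decrement y* with logit mean
    link and precision phi; same random-effect structure; marginal
    likelihood by adaptive Gauss–Hermite quadrature.
``twopart_beta``
    Zero-inflated (two-part) beta model: a mixed logistic model for the
    probability that the decrement is exactly zero (utility at the
    ceiling), with its own independent random intercept, combined with a
    mixed beta regression of the positive decrements.  Because the two
    parts share no parameters or random effects, their likelihoods
    factorise and are maximised separately.
``aldvmm``
    Adjusted limited dependent variable mixture model: K normal
    components on the utility scale with shared covariate effects,
    per-class intercepts and SDs, class probabilities, censoring masses
    at the bounds (ceiling threshold psi1), and a shared patient random
    intercept.

Fixed effects always comprise an intercept, the chosen baseline
covariates, and the two piecewise-linear time slopes (before/after the
knot at 1 year post-transplantation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit

from .data import CohortData, FINAL_MODEL_COVARIATES, build_design, prepare_cohort
from .errors import ConfigError, ConvergenceError, DataError, NumericalError
from .families import AldvmmObs, BernoulliZeroObs, BetaObs, GaussianObs
from .lmm import LmmData, fit_lmm_ml
from .quadrature import AghIntegrator
from .transforms import TransformSpec, back_transform, compress, rescale_to_decrement, time_basis

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "FittedModel",
    "fit_model",
    "predict_utility",
    "information_criteria",
    "linear_predictor",
    "obs_loglik_conditional",
    "loglik_marginal_quadrature",
]

FAMILIES = ("lmm", "beta", "twopart_beta", "aldvmm")

_BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """Family, covariate coding and random-effect structure of one model.

    ``random_slope`` controls the random slope on t_pre in the main
    (conditional) part; the two-part zero part always uses a single
    independent random intercept and the mixture family a single shared
    random intercept.  ``psi1`` is the ALDVMM ceiling threshold on the
    utility scale (default 0.9, or the largest attainable value-set
    utility strictly below u_max when a value set is in play).
    """

    family: str = "lmm"
    covariates: tuple[str, ...] = FINAL_MODEL_COVARIATES
    random_slope: bool = True
    estimate_corr: bool = False
    n_classes: int = 1
    psi1: float | None = None
    n_nodes: int = 9
    knot: float = 1.0
    u_min: float = -0.53
    u_max: float = 1.0
    centering: tuple[tuple[str, float], ...] | None = None
    n_starts: int = 10

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.n_classes < 1:
            raise ConfigError("n_classes must be >= 1")
        if self.family == "aldvmm" and self.n_classes >= 3:
            warnings.warn(
                "ALDVMM with >= 3 classes is experimental (convergence is fragile "
                "at typical cohort sizes)",
                stacklevel=2,
            )
        if self.psi1 is not None and self.psi1 >= self.u_max:
            raise ConfigError("psi1 must lie strictly below u_max")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def psi1_value(self) -> float:
        return 0.9 if self.psi1 is None else float(self.psi1)

    @property
    def centering_map(self) -> dict[str, float] | None:
        return dict(self.centering) if self.centering else None

    def transform_spec(self, n_obs: int) -> TransformSpec:
        return TransformSpec(self.u_min, self.u_max, max(n_obs, 2))


@dataclass
class FittedModel:
    """Estimates, variance components and diagnostics of one fitted model."""

    spec: ModelSpec
    coefficients: dict[str, float]
    variance_components: dict
    loglik: float
    n_params: int
    n_obs: int
    n_patients: int
    zero_coefficients: dict[str, float] | None = None
    class_intercepts: list[float] | None = None
    converged: bool = True
    grad_norm: float = float("nan")
    n_iter: int = 0
    n_excluded_patients: int = 0
    n_excluded_obs: int = 0
    beta_cov: list | None = None
    extras: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"]["covariates"] = list(self.spec.covariates)
        if d["spec"]["centering"] is not None:
            d["spec"]["centering"] = [list(pair) for pair in d["spec"]["centering"]]
        d["aic"] = self.aic
        d["bic"] = self.bic
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        d = dict(d)
        d.pop("aic", None)
        d.pop("bic", None)
        spec_d = dict(d.pop("spec"))
        spec_d["covariates"] = tuple(spec_d["covariates"])
        if spec_d.get("centering") is not None:
            spec_d["centering"] = tuple(tuple(pair) for pair in spec_d["centering"])
        return cls(spec=ModelSpec(**spec_d), **d)

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def information_criteria(fm: FittedModel) -> tuple[float, float]:
    """AIC = -2 l + 2p and BIC = -2 l + p log(n_obs)."""
    return fm.aic, fm.bic


# ---------------------------------------------------------------------
# linear predictor & conditional densities (building blocks)
# ---------------------------------------------------------------------


def linear_predictor(
    x: Mapping[str, float],
    t: float | np.ndarray,
    coefficients: Mapping[str, float],
    knot: float = 1.0,
) -> float | np.ndarray:
    """eta = b0 + sum_k b_k x_k + b_pre t_pre + b_post t_post.

    ``coefficients`` maps design names (``intercept``, covariates,
    ``t_pre``, ``t_post``) to values; every covariate named there must
    be present in ``x``.
    """
    t_pre, t_post = time_basis(np.asarray(t, dtype=float), knot=knot)
    eta = 0.0
    for name, beta in coefficients.items():
        if name == "intercept":
            eta = eta + beta
        elif name == "t_pre":
            eta = eta + beta * t_pre
        elif name == "t_post":
            eta = eta + beta * t_post
        else:
            if name not in x:
                raise DataError(f"covariate {name!r} required by the model is missing")
            eta = eta + beta * float(x[name])
    return eta


def obs_loglik_conditional(u, eta, b, spec: ModelSpec, theta: Mapping) -> np.ndarray:
    """Per-observation conditional log-density given the random effects.

    ``eta`` is the fixed-effect linear predictor of the main part on the
    family's natural scale and ``b`` the realised random-effect
    contribution added to it.  Family-specific entries of ``theta``:
    ``sd_resid`` (lmm); ``phi`` and ``n_compress`` (beta families);
    ``eta_zero``/``b_zero`` (two-part zero part); ``class_intercepts``,
    ``class_sigmas``, ``class_probs`` (aldvmm).
    """
    u = np.asarray(u, dtype=float)
    eta_b = np.asarray(eta, dtype=float) + np.asarray(b, dtype=float)
    tspec = spec.transform_spec(int(theta.get("n_compress", 2)))
    if spec.family == "lmm":
        return GaussianObs(u, theta["sd_resid"]).logpdf(eta_b)
    if np.any(u < spec.u_min - _BOUNDARY_TOL) or np.any(u > spec.u_max + _BOUNDARY_TOL):
        raise DataError("utility outside the attainable range")
    if spec.family == "beta":
        y_star = compress(rescale_to_decrement(u, tspec), tspec)
        return BetaObs(np.atleast_1d(y_star), theta["phi"]).logpdf(eta_b)
    if spec.family == "twopart_beta":
        y = np.atleast_1d(rescale_to_decrement(u, tspec))
        eta_zero = np.asarray(theta["eta_zero"], dtype=float) + np.asarray(
            theta.get("b_zero", 0.0), dtype=float
        )
        log_p0 = BernoulliZeroObs(np.ones_like(y)).logpdf(eta_zero)
        log_1mp0 = BernoulliZeroObs(np.zeros_like(y)).logpdf(eta_zero)
        out = np.where(y == 0, log_p0, log_1mp0)
        pos = y > 0
        if np.any(pos):
            y_star = compress(y[pos], tspec)
            out = out.astype(float)
            out[pos] += BetaObs(y_star, theta["phi"]).logpdf(np.broadcast_to(eta_b, y.shape)[pos])
        return out
    # aldvmm
    fam = AldvmmObs(
        np.atleast_1d(u),
        np.asarray(theta["class_intercepts"], float),
        np.asarray(theta["class_sigmas"], float),
        np.asarray(theta["class_probs"], float),
        psi1=theta.get("psi1", spec.psi1_value),
        u_min=spec.u_min,
        u_max=spec.u_max,
    )
    return fam.logpdf(eta_b)


# ---------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------


def _as_cohort(data, spec: ModelSpec) -> CohortData:
    if isinstance(data, CohortData):
        return data
    if isinstance(data, pd.DataFrame):
        # the linear family lives on the unbounded scale (unclamped
        # simulator output stays fittable); bounded families validate
        return prepare_cohort(
            data,
            spec.covariates,
            u_min=spec.u_min,
            u_max=spec.u_max,
            check_range=spec.family != "lmm",
        )
    raise DataError("data must be a DataFrame or CohortData")


def _design(cohort: CohortData, spec: ModelSpec):
    X, names = build_design(
        cohort.df, spec.covariates, knot=spec.knot, centering=spec.centering_map
    )
    u = cohort.df["hsuv"].to_numpy(float)
    codes = cohort.patient_index()
    t_pre = X[:, names.index("t_pre")]
    if spec.random_slope:
        Z = np.column_stack([np.ones(len(u)), t_pre])
    else:
        Z = np.ones((len(u), 1))
    return X, names, u, codes, Z


def _G_from_sds(sd0, sd1=None, rho=0.0):
    if sd1 is None:
        return np.array([[sd0**2]])
    return np.array([[sd0**2, rho * sd0 * sd1], [rho * sd0 * sd1, sd1**2]])


# ---------------------------------------------------------------------
# loglik at explicit parameter values (quadrature path)
# ---------------------------------------------------------------------


def _beta_arr(theta_beta, names):
    if isinstance(theta_beta, Mapping):
        return np.array([theta_beta[n] for n in names], dtype=float)
    return np.asarray(theta_beta, dtype=float)


def loglik_marginal_quadrature(data, spec: ModelSpec, theta: Mapping, n_nodes: int | None = None) -> float:
    """Marginal log-likelihood at explicit parameter values.

    Integrates the random effects by adaptive Gauss–Hermite quadrature
    for every family (including ``lmm``, for which
    :func:`hsuvmix.lmm.loglik_closed_form` is the exact reference).
    ``theta`` uses natural-scale entries: ``beta`` (array or name->value
    mapping), ``sd_intercept``, ``sd_slope``, ``corr``, ``sd_resid``,
    ``phi``, ``gamma``/``sd_zero_intercept`` (two-part), and the aldvmm
    class parameters.
    """
    cohort = _as_cohort(data, spec)
    X, names, u, codes, Z = _design(cohort, spec)
    nodes = n_nodes or spec.n_nodes
    if spec.family == "lmm":
        beta = _beta_arr(theta["beta"], names)
        G = _G_from_sds(
            theta["sd_intercept"],
            theta.get("sd_slope") if spec.random_slope else None,
            theta.get("corr", 0.0) or 0.0,
        )
        fam = GaussianObs(u, theta["sd_resid"])
        return AghIntegrator(Z, codes, nodes).loglik(fam, X @ beta, G)
    if spec.family == "beta":
        beta = _beta_arr(theta["beta"], names)
        tspec = spec.transform_spec(len(u))
        y_star = compress(rescale_to_decrement(u, tspec), tspec)
        G = _G_from_sds(
            theta["sd_intercept"],
            theta.get("sd_slope") if spec.random_slope else None,
            theta.get("corr", 0.0) or 0.0,
        )
        fam = BetaObs(y_star, theta["phi"])
        return AghIntegrator(Z, codes, nodes).loglik(fam, X @ beta, G)
    if spec.family == "twopart_beta":
        return _twopart_loglik(cohort, spec, theta, nodes)
    # aldvmm: shared random intercept, shared covariate slopes, class intercepts
    beta = _beta_arr(theta["beta"], names[1:])  # no shared intercept
    fam = AldvmmObs(
        u,
        np.asarray(theta["class_intercepts"], float),
        np.asarray(theta["class_sigmas"], float),
        np.asarray(theta["class_probs"], float),
        psi1=theta.get("psi1", spec.psi1_value),
        u_min=spec.u_min,
        u_max=spec.u_max,
    )
    Zb = np.ones((len(u), 1))
    G = np.array([[theta["sd_intercept"] ** 2]])
    return AghIntegrator(Zb, codes, nodes).loglik(fam, X[:, 1:] @ beta, G)


def _twopart_loglik(cohort: CohortData, spec: ModelSpec, theta: Mapping, nodes: int) -> float:
    X, names, u, codes, Z = _design(cohort, spec)
    y = rescale_to_decrement(u, TransformSpec(spec.u_min, spec.u_max, 2))
    is_zero = y <= _BOUNDARY_TOL
    gamma = _beta_arr(theta["gamma"], names)
    ll_zero = AghIntegrator(np.ones((len(u), 1)), codes, nodes).loglik(
        BernoulliZeroObs(is_zero),
        X @ gamma,
        np.array([[theta["sd_zero_intercept"] ** 2]]),
    )
    pos = ~is_zero
    if not np.any(pos):
        return ll_zero
    tspec = spec.transform_spec(int(pos.sum()))
    y_star = compress(y[pos], tspec)
    beta = _beta_arr(theta["beta"], names)
    G = _G_from_sds(
        theta["sd_intercept"],
        theta.get("sd_slope") if spec.random_slope else None,
        theta.get("corr", 0.0) or 0.0,
    )
    ll_cond = AghIntegrator(Z[pos], codes[pos], nodes).loglik(
        BetaObs(y_star, theta["phi"]), X[pos] @ beta, G
    )
    return ll_zero + ll_cond


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------


def _optimize(negloglik, x0, max_iter=600, n_polish=3):
    """L-BFGS-B with polish restarts (a fresh Hessian approximation often
    finishes what a stalled line search left behind)."""
    res = optimize.minimize(
        negloglik,
        x0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-7},
    )
    for _ in range(n_polish):
        rel = np.max(np.abs(res.jac)) / (1.0 + abs(float(res.fun)))
        if not np.isfinite(res.fun) or rel <= 1e-4:
            break
        nxt = optimize.minimize(
            negloglik,
            res.x,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
        )
        if not np.isfinite(nxt.fun) or nxt.fun > res.fun - 1e-10:
            if np.isfinite(nxt.fun) and nxt.fun <= res.fun:
                res = nxt
            break
        res = nxt
    return res


def _check_convergence(res, label):
    if not np.isfinite(res.fun):
        raise ConvergenceError(f"{label} fit diverged", {"result": str(res)})
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    rel = grad_norm / (1.0 + abs(float(res.fun)))
    if rel > 1e-2:
        raise ConvergenceError(
            f"{label} fit did not converge (relative gradient norm {rel:.2e})",
            {"grad_norm": grad_norm, "loglik": -float(res.fun), "message": str(res.message)},
        )
    return grad_norm


def fit_model(data, spec: ModelSpec, init: Mapping | None = None, seed: int | None = None) -> FittedModel:
    """Maximum marginal likelihood fit of one model family.

    Rows with missing values on the model's covariates are dropped
    (complete-case) and counted.  The lmm uses the closed-form profiled
    likelihood; the other families use adaptive Gauss–Hermite
    quadrature with an unconstrained reparameterisation (log SDs, log
    phi, logit-simplex class probabilities).  The mixture family runs a
    seeded multi-start and orders the classes by intercept.
    """
    cohort = _as_cohort(data, spec)
    if cohort.n_obs == 0:
        raise DataError("no complete-case observations to fit on")
    if spec.family == "lmm":
        fm = _fit_lmm(cohort, spec, init)
    elif spec.family == "beta":
        fm = _fit_beta(cohort, spec, init)
    elif spec.family == "twopart_beta":
        fm = _fit_twopart(cohort, spec, init)
    else:
        fm = _fit_aldvmm(cohort, spec, init, seed)
    fm.n_excluded_patients = cohort.n_excluded_patients
    fm.n_excluded_obs = cohort.n_excluded_obs
    return fm


def _fit_lmm(cohort, spec, init):
    X, names, u, codes, Z = _design(cohort, spec)
    res = fit_lmm_ml(
        LmmData(X, u, Z, codes),
        random_slope=spec.random_slope,
        estimate_corr=spec.estimate_corr,
        theta0=np.asarray(init["theta"], float) if init and "theta" in init else None,
    )
    n_theta = 2 + (1 if spec.random_slope else 0) + (
        1 if (spec.random_slope and spec.estimate_corr) else 0
    )
    vc = {
        "sd_intercept": float(res["sd_intercept"]),
        "sd_slope": float(res["sd_slope"]) if spec.random_slope else None,
        "corr": res["corr"],
        "sd_resid": float(res["sd_resid"]),
    }
    return FittedModel(
        spec=spec,
        coefficients=dict(zip(names, map(float, res["beta"]))),
        variance_components=vc,
        loglik=res["loglik"],
        n_params=len(names) + n_theta,
        n_obs=cohort.n_obs,
        n_patients=cohort.n_patients,
        converged=res["converged"],
        grad_norm=res["grad_norm"],
        n_iter=res["n_iter"],
        beta_cov=res["beta_cov"].tolist(),
    )


def _logit_lstsq(X, y01):
    """Crude logit-scale least-squares start values."""
    z = np.log(np.clip(y01, 1e-6, 1 - 1e-6) / np.clip(1 - y01, 1e-6, 1 - 1e-6))
    return np.linalg.lstsq(X, z, rcond=None)[0]


def _fit_beta(cohort, spec, init):
    X, names, u, codes, Z = _design(cohort, spec)
    tspec = spec.transform_spec(len(u))
    y_star = compress(rescale_to_decrement(u, tspec), tspec)
    p = X.shape[1]
    has_slope = spec.random_slope

    def unpack(x):
        beta = x[:p]
        sd0 = np.exp(x[p])
        sd1 = np.exp(x[p + 1]) if has_slope else None
        phi = np.exp(x[-1])
        return beta, sd0, sd1, phi

    def make_negloglik(integ):
        def negloglik(x):
            beta, sd0, sd1, phi = unpack(x)
            try:
                ll = integ.loglik(BetaObs(y_star, phi), X @ beta, _G_from_sds(sd0, sd1))
            except (NumericalError, FloatingPointError, np.linalg.LinAlgError):
                return 1e12
            return -ll if np.isfinite(ll) else 1e12
        return negloglik

    if init and "x0" in init:
        x0 = np.asarray(init["x0"], float)
    else:
        beta0 = _logit_lstsq(X, y_star)
        x0 = np.r_[beta0, np.log(0.5), *([np.log(0.5)] if has_slope else []), np.log(5.0)]
    negloglik = make_negloglik(AghIntegrator(Z, codes, spec.n_nodes))
    res = _optimize(negloglik, x0)
    grad_norm = _check_convergence(res, "mixed beta")
    beta, sd0, sd1, phi = unpack(res.x)
    return FittedModel(
        spec=spec,
        coefficients=dict(zip(names, map(float, beta))),
        variance_components={
            "sd_intercept": float(sd0),
            "sd_slope": float(sd1) if has_slope else None,
            "corr": None,
            "phi": float(phi),
        },
        loglik=-float(res.fun),
        n_params=len(res.x),
        n_obs=cohort.n_obs,
        n_patients=cohort.n_patients,
        converged=bool(res.success),
        grad_norm=grad_norm,
        n_iter=int(res.nit),
        extras={"n_compress": len(u)},
    )


def _fit_twopart(cohort, spec, init):
    X, names, u, codes, Z = _design(cohort, spec)
    y = rescale_to_decrement(u, TransformSpec(spec.u_min, spec.u_max, 2))
    is_zero = y <= _BOUNDARY_TOL
    p = X.shape[1]

    # -- zero part: mixed logistic with one random intercept
    integ_z = AghIntegrator(np.ones((len(u), 1)), codes, spec.n_nodes)
    fam_z = BernoulliZeroObs(is_zero)

    def negloglik_zero(x):
        gamma, sdz = x[:p], np.exp(x[p])
        try:
            ll = integ_z.loglik(fam_z, X @ gamma, np.array([[sdz**2]]))
        except (NumericalError, FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    gamma0 = _logit_lstsq(X, is_zero.astype(float) * 0.8 + 0.1)
    x0_z = np.r_[gamma0, np.log(1.0)]
    if init and "x0_zero" in init:
        x0_z = np.asarray(init["x0_zero"], float)
    res_z = _optimize(negloglik_zero, x0_z)
    grad_z = _check_convergence(res_z, "two-part zero part")
    gamma, sd_zero = res_z.x[:p], float(np.exp(res_z.x[p]))

    # -- conditional part: mixed beta on the positive decrements,
    #    compressed with N = number of positive observations
    pos = ~is_zero
    if not np.any(pos):
        raise DataError("two-part model needs at least one positive decrement")
    n_pos = int(pos.sum())
    tspec = spec.transform_spec(n_pos)
    y_star = compress(y[pos], tspec)
    X_pos, Z_pos, codes_pos = X[pos], Z[pos], codes[pos]
    has_slope = spec.random_slope

    def unpack_c(x):
        beta = x[:p]
        sd0 = np.exp(x[p])
        sd1 = np.exp(x[p + 1]) if has_slope else None
        phi = np.exp(x[-1])
        return beta, sd0, sd1, phi

    def make_negloglik_cond(integ_c):
        def negloglik_cond(x):
            beta, sd0, sd1, phi = unpack_c(x)
            try:
                ll = integ_c.loglik(BetaObs(y_star, phi), X_pos @ beta, _G_from_sds(sd0, sd1))
            except (NumericalError, FloatingPointError, np.linalg.LinAlgError):
                return 1e12
            return -ll if np.isfinite(ll) else 1e12
        return negloglik_cond

    beta0 = _logit_lstsq(X_pos, y_star)
    x0_c = np.r_[beta0, np.log(0.5), *([np.log(0.5)] if has_slope else []), np.log(5.0)]
    if init and "x0_cond" in init:
        x0_c = np.asarray(init["x0_cond"], float)
    negloglik_cond = make_negloglik_cond(AghIntegrator(Z_pos, codes_pos, spec.n_nodes))
    res_c = _optimize(negloglik_cond, x0_c)
    grad_c = _check_convergence(res_c, "two-part conditional part")
    beta, sd0, sd1, phi = unpack_c(res_c.x)

    loglik = -(float(res_z.fun) + float(res_c.fun))
    return FittedModel(
        spec=spec,
        coefficients=dict(zip(names, map(float, beta))),
        zero_coefficients=dict(zip(names, map(float, gamma))),
        variance_components={
            "sd_intercept": float(sd0),
            "sd_slope": float(sd1) if has_slope else None,
            "corr": None,
            "phi": float(phi),
            "sd_zero_intercept": sd_zero,
        },
        loglik=loglik,
        n_params=len(res_z.x) + len(res_c.x),
        n_obs=cohort.n_obs,
        n_patients=cohort.n_patients,
        converged=bool(res_z.success and res_c.success),
        grad_norm=float(max(grad_z, grad_c)),
        n_iter=int(res_z.nit + res_c.nit),
        extras={"n_compress": n_pos, "n_zero": int(is_zero.sum())},
    )


def _simplex_from_logits(logits):
    full = np.r_[logits, 0.0]
    e = np.exp(full - full.max())
    return e / e.sum()


def _fit_aldvmm(cohort, spec, init, seed):
    X, names, u, codes, Z = _design(cohort, spec)
    K = spec.n_classes
    p_shared = X.shape[1] - 1  # covariates + two slopes, intercepts are per class
    X_shared = X[:, 1:]
    integ = AghIntegrator(np.ones((len(u), 1)), codes, spec.n_nodes)
    psi1 = spec.psi1_value

    def unpack(x):
        alphas = x[:K]
        beta = x[K : K + p_shared]
        # floor keeps a component from collapsing onto a data atom
        # (the unbounded-likelihood degeneracy of normal mixtures);
        # 0.01 is ~1% of the utility scale, well below any plausible
        # residual SD
        sigmas = 0.01 + np.exp(x[K + p_shared : K + p_shared + K])
        if K > 1:
            pis = _simplex_from_logits(x[K + p_shared + K : K + p_shared + 2 * K - 1])
        else:
            pis = np.ones(1)
        sd_b = np.exp(x[-1])
        return alphas, beta, sigmas, pis, sd_b

    def negloglik(x):
        alphas, beta, sigmas, pis, sd_b = unpack(x)
        try:
            fam = AldvmmObs(u, alphas, sigmas, pis, psi1, spec.u_min, spec.u_max)
            ll = integ.loglik(fam, X_shared @ beta, np.array([[sd_b**2]]))
        except (NumericalError, FloatingPointError, np.linalg.LinAlgError, DataError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    # base start: random-intercept lmm
    base = fit_lmm_ml(LmmData(X, u, np.ones((len(u), 1)), codes), random_slope=False)
    beta_lmm = base["beta"]
    rng = np.random.default_rng(seed)
    n_starts = 1 if K == 1 else spec.n_starts
    best = None
    fallback = None
    for s in range(n_starts):
        offsets = np.linspace(-0.15, 0.15, K) if K > 1 else np.zeros(1)
        jitter = rng.normal(0, 0.1, K) if s > 0 else 0.0
        alphas0 = beta_lmm[0] + offsets + jitter
        x0 = np.r_[
            alphas0,
            beta_lmm[1:],
            np.log(np.full(K, max(base["sd_resid"], 1e-2)))
            + (rng.normal(0, 0.3, K) if s > 0 else 0.0),
            np.zeros(K - 1),
            np.log(max(base["sd_intercept"], 1e-2)),
        ]
        if init and "x0" in init and s == 0:
            x0 = np.asarray(init["x0"], float)
        res = _optimize(negloglik, x0)
        if not np.isfinite(res.fun):
            continue
        rel = np.max(np.abs(res.jac)) / (1.0 + abs(float(res.fun)))
        if rel > 1e-2:  # spurious spiky optimum; keep only as fallback
            if best is None and (fallback is None or res.fun < fallback.fun):
                fallback = res
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        diag = {"n_starts": n_starts}
        if fallback is not None:
            diag.update(best_loglik=-float(fallback.fun),
                        grad_norm=float(np.max(np.abs(fallback.jac))))
        raise ConvergenceError(
            f"no ALDVMM start converged (K={K}, {n_starts} starts)", diag
        )
    grad_norm = _check_convergence(best, "mixed ALDVMM")
    alphas, beta, sigmas, pis, sd_b = unpack(best.x)
    order = np.argsort(alphas)  # resolve label switching
    alphas, sigmas, pis = alphas[order], sigmas[order], pis[order]
    return FittedModel(
        spec=spec,
        coefficients=dict(zip(names[1:], map(float, beta))),
        class_intercepts=[float(a) for a in alphas],
        variance_components={
            "sd_intercept": float(sd_b),
            "sd_slope": None,
            "corr": None,
            "class_sigmas": [float(s) for s in sigmas],
            "class_probs": [float(w) for w in pis],
            "psi1": psi1,
        },
        loglik=-float(best.fun),
        n_params=len(best.x),
        n_obs=cohort.n_obs,
        n_patients=cohort.n_patients,
        converged=bool(best.success),
        grad_norm=grad_norm,
        n_iter=int(best.nit),
    )


# ---------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------

_GH_T, _GH_W = hermgauss(21)
_GH_W = _GH_W / np.sqrt(np.pi)


def _gauss_mean(f, sd):
    """E[f(xi)] for xi ~ N(0, sd^2) by 21-node Gauss–Hermite."""
    x = np.sqrt(2.0) * sd * _GH_T
    return np.tensordot(np.stack([np.asarray(f(v), float) for v in x]), _GH_W, axes=(0, 0))


def predict_utility(
    fm: FittedModel,
    x: Mapping[str, float],
    t,
    mode: str = "conditional_b0",
):
    """Predicted utility for covariate profile ``x`` at time(s) ``t``.

    ``conditional_b0`` evaluates at zero random effects (the population
    reference patient); ``marginal`` averages the nonlinear families
    over the random-effect distribution.  Predictions are clamped to
    [u_min, u_max].
    """
    if mode not in ("conditional_b0", "marginal"):
        raise ConfigError(f"unknown prediction mode {mode!r}")
    spec = fm.spec
    t = np.asarray(t, dtype=float)
    vc = fm.variance_components
    tspec = TransformSpec(spec.u_min, spec.u_max, 2)
    if spec.centering_map:
        x = {k: v - spec.centering_map.get(k, 0.0) for k, v in x.items()}

    def slope_sd(t_arr):
        sd0 = vc.get("sd_intercept") or 0.0
        sd1 = vc.get("sd_slope") or 0.0
        t_pre, _ = time_basis(t_arr, knot=spec.knot)
        return np.sqrt(sd0**2 + (sd1 * t_pre) ** 2)

    if spec.family == "lmm":
        eta = linear_predictor(x, t, fm.coefficients, knot=spec.knot)
        return np.clip(eta, spec.u_min, spec.u_max)

    if spec.family == "beta":
        eta = np.asarray(linear_predictor(x, t, fm.coefficients, knot=spec.knot), float)
        if mode == "marginal":
            sd = slope_sd(t)
            mu = np.array(
                [_gauss_mean(lambda v: expit(e + v), s) for e, s in zip(np.atleast_1d(eta), np.atleast_1d(sd))]
            ).reshape(np.shape(eta))
        else:
            mu = expit(eta)
        return np.clip(back_transform(mu, tspec), spec.u_min, spec.u_max)

    if spec.family == "twopart_beta":
        eta_y = np.asarray(linear_predictor(x, t, fm.coefficients, knot=spec.knot), float)
        eta_z = np.asarray(linear_predictor(x, t, fm.zero_coefficients, knot=spec.knot), float)
        if mode == "marginal":
            sd_z = vc.get("sd_zero_intercept") or 0.0
            p0 = np.array(
                [_gauss_mean(lambda v: expit(e + v), sd_z) for e in np.atleast_1d(eta_z)]
            ).reshape(np.shape(eta_z))
            sd = slope_sd(t)
            mu = np.array(
                [_gauss_mean(lambda v: expit(e + v), s) for e, s in zip(np.atleast_1d(eta_y), np.atleast_1d(sd))]
            ).reshape(np.shape(eta_y))
        else:
            p0 = expit(eta_z)
            mu = expit(eta_y)
        decrement = (1.0 - p0) * mu
        return np.clip(back_transform(decrement, tspec), spec.u_min, spec.u_max)

    # aldvmm
    eta = np.asarray(
        linear_predictor({**x}, t, {**fm.coefficients}, knot=spec.knot), float
    )
    fam = AldvmmObs(
        np.zeros(1),
        np.asarray(fm.class_intercepts, float),
        np.asarray(vc["class_sigmas"], float),
        np.asarray(vc["class_probs"], float),
        psi1=vc.get("psi1", spec.psi1_value),
        u_min=spec.u_min,
        u_max=spec.u_max,
    )

    def mixture_mean(e):
        means = fam.component_means(np.asarray(e, float))
        return means @ np.asarray(vc["class_probs"], float)

    if mode == "marginal":
        sd_b = vc.get("sd_intercept") or 0.0
        out = np.array(
            [_gauss_mean(lambda v: mixture_mean(e + v), sd_b) for e in np.atleast_1d(eta)]
        ).reshape(np.shape(eta))
    else:
        out = mixture_mean(eta)
    return np.clip(out, spec.u_min, spec.u_max)
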