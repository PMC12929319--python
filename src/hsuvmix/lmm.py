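"""Closed-form marginal likelihood and ML fit of the linear mixed model.

With a random intercept and (optionally) a random slope on the pre-knot
time basis, the repeated utilities of patient i are jointly normal,

    u_i ~ N(X_i beta, V_i),   V_i = Z_i G Z_i' + sigma^2 I,

so the marginal log-likelihood is available in closed form and beta can
be profiled out by generalised least squares given the variance
components.  The optimiser therefore works on at most four parameters
(log SDs, optionally the random-effect correlation on the atanh scale),
which keeps fits at cohort scale (thousands of patients) in seconds.

Patients are batched by cluster size so all linear algebra runs through
numpy's batched Cholesky routines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, NumericalError

__all__ = ["LmmData", "profiled_loglik", "loglik_closed_form", "fit_lmm_ml"]


@dataclass
class LmmData:
    """Design blocks of one cohort, grouped by cluster size for batching."""

    X: np.ndarray
    y: np.ndarray
    Z: np.ndarray
    codes: np.ndarray  # dense patient codes, rows sorted by patient

    def __post_init__(self):
        starts = np.flatnonzero(np.r_[True, np.diff(self.codes) != 0])
        sizes = np.diff(np.r_[starts, len(self.codes)])
        self._groups = []
        for m in np.unique(sizes):
            sel = starts[sizes == m]
            rows = (sel[:, None] + np.arange(m)[None, :]).ravel()
            B = len(sel)
            self._groups.append(
                (
                    int(m),
                    self.X[rows].reshape(B, m, -1),
                    self.y[rows].reshape(B, m),
                    self.Z[rows].reshape(B, m, -1),
                )
            )
        self.n_obs = len(self.y)
        self.n_patients = len(starts)
        self.p = self.X.shape[1]
        self.q = self.Z.shape[1]


def _variance_matrices(data: LmmData, G: np.ndarray, sigma2: float):
    """Yield per-size-group (Xg, yg, cholesky(Vg))."""
    for m, Xg, yg, Zg in data._groups:
        V = Zg @ G @ np.swapaxes(Zg, 1, 2) + sigma2 * np.eye(m)
        try:
            C = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("implied covariance not positive definite") from exc
        yield Xg, yg, C


def profiled_loglik(data: LmmData, G: np.ndarray, sigma2: float):
    """Profile beta out by GLS; return (loglik, beta_hat, XtViX).

    loglik is the marginal normal log-likelihood at (beta_hat, G, sigma2).
    """
    p = data.p
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    pieces = []
    for Xg, yg, C in _variance_matrices(data, G, sigma2):
        logdet += 2.0 * np.log(np.diagonal(C, axis1=1, axis2=2)).sum()
        Wx = np.linalg.solve(C, Xg)  # (B, m, p) whitened
        Wy = np.linalg.solve(C, yg[..., None])[..., 0]  # (B, m)
        XtViX += np.einsum("bmp,bmq->pq", Wx, Wx)
        XtViy += np.einsum("bmp,bm->p", Wx, Wy)
        ytViy += float((Wy * Wy).sum())
        pieces.append((Wx, Wy))
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular fixed-effects design (collinear covariates?)") from exc
    rss = ytViy - beta @ XtViy
    ll = -0.5 * (data.n_obs * np.log(2.0 * np.pi) + logdet + rss)
    return ll, beta, XtViX


def loglik_closed_form(data: LmmData, beta: np.ndarray, G: np.ndarray, sigma2: float) -> float:
    """Exact marginal log-likelihood at given fixed effects and variances."""
    ll = -0.5 * data.n_obs * np.log(2.0 * np.pi)
    for Xg, yg, C in _variance_matrices(data, G, sigma2):
        r = yg - np.einsum("bmp,p->bm", Xg, beta)
        Wr = np.linalg.solve(C, r[..., None])[..., 0]
        ll -= np.log(np.diagonal(C, axis1=1, axis2=2)).sum()
        ll -= 0.5 * float((Wr * Wr).sum())
    return float(ll)


def _unpack_theta(theta, random_slope, estimate_corr):
    sd0 = np.exp(theta[0])
    idx = 1
    if random_slope:
        sd1 = np.exp(theta[idx])
        idx += 1
    else:
        sd1 = None
    rho = 0.0
    if random_slope and estimate_corr:
        rho = np.tanh(theta[idx])
        idx += 1
    sigma = np.exp(theta[idx])
    if random_slope:
        G = np.array(
            [[sd0**2, rho * sd0 * sd1], [rho * sd0 * sd1, sd1**2]]
        )
    else:
        G = np.array([[sd0**2]])
    return G, sigma, (sd0, sd1, rho)


def fit_lmm_ml(
    data: LmmData,
    random_slope: bool = True,
    estimate_corr: bool = False,
    theta0: np.ndarray | None = None,
):
    """Maximum-likelihood fit of the linear mixed model.

    Returns a dict with fixed effects, variance components (SDs on the
    natural scale), the maximised log-likelihood, convergence
    diagnostics and the (beta, theta) parameterisation details needed
    for standard errors.
    """
    n_theta = 2 + (1 if random_slope else 0) + (1 if (random_slope and estimate_corr) else 0)
    if theta0 is None:
        sd_y = max(float(np.std(data.y)), 1e-3)
        theta0 = np.full(n_theta, np.log(sd_y / np.sqrt(2.0)))
        if random_slope and estimate_corr:
            theta0[2] = 0.0  # atanh(rho) slot starts at zero correlation

    def negloglik(theta):
        G, sigma, _ = _unpack_theta(theta, random_slope, estimate_corr)
        try:
            ll, _, _ = profiled_loglik(data, G, sigma**2)
        except NumericalError:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(
        negloglik, theta0, method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-12}
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError("linear mixed model fit diverged", {"result": str(res)})
    G, sigma, (sd0, sd1, rho) = _unpack_theta(res.x, random_slope, estimate_corr)
    ll, beta, XtViX = profiled_loglik(data, G, sigma**2)
    return {
        "beta": beta,
        "beta_cov": np.linalg.inv(XtViX),
        "G": G,
        "sd_intercept": sd0,
        "sd_slope": sd1,
        "corr": rho if (random_slope and estimate_corr) else None,
        "sd_resid": sigma,
        "loglik": float(ll),
        "theta": res.x,
        "converged": bool(res.success),
        "grad_norm": float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
        "n_iter": int(res.nit),
    }
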