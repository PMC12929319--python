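"""Per-observation conditional log-densities for the four model families.

Each family binds the observed outcomes and its auxiliary parameters at
construction and exposes the conditional log-density and its first two
derivatives with respect to the observation-level linear predictor
``eta`` (which already includes the random-effect contribution).  These
derivatives drive the Newton mode search of the adaptive Gauss–Hermite
integration.

Families
--------
GaussianObs
    Linear mixed model residual density on the utility scale.
BetaObs
    Beta density of the compressed decrement with logit mean link and
    precision phi: shapes (mu phi, (1 - mu) phi).
BernoulliZeroObs
    Zero-part of the two-part model: probability that the raw decrement
    is exactly zero (utility at the ceiling), logit link.
AldvmmObs
    K-component mixture of normals on the utility scale with probability
    masses at the bounds induced by censoring: latent values above the
    ceiling threshold psi1 are observed as u_max, values below u_min as
    u_min, interior values as themselves.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, log_expit, log_ndtr, ndtr, polygamma, psi

from .errors import DataError

__all__ = ["GaussianObs", "BetaObs", "BernoulliZeroObs", "AldvmmObs"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(z):
    return -0.5 * z * z - _LOG_SQRT_2PI


def _mills(z):
    """Inverse Mills ratio phi(z)/Phi(z), stable in the deep left tail."""
    z = np.asarray(z, dtype=float)
    zs = np.maximum(z, -25.0)
    out = np.exp(_norm_logpdf(zs) - log_ndtr(zs))
    # phi/Phi ~ -z + O(1/z) as z -> -inf
    return np.where(z > -25.0, out, -z)


class GaussianObs:
    """Normal conditional density of utilities around ``eta`` with SD sigma."""

    def __init__(self, u: np.ndarray, sigma: float):
        if sigma <= 0:
            raise DataError("residual SD must be positive")
        self.u = np.asarray(u, dtype=float)
        self.sigma = float(sigma)

    def logpdf(self, eta):
        z = (self.u - eta) / self.sigma
        return -0.5 * z * z - np.log(self.sigma) - _LOG_SQRT_2PI

    def d1(self, eta):
        return (self.u - eta) / self.sigma**2

    def d2(self, eta):
        return np.full_like(np.asarray(eta, float), -1.0 / self.sigma**2)


class BetaObs:
    """Beta log-density of compressed decrements with logit-mean link."""

    def __init__(self, y_star: np.ndarray, phi: float):
        y_star = np.asarray(y_star, dtype=float)
        if np.any(y_star <= 0) or np.any(y_star >= 1):
            raise DataError("compressed decrements must lie strictly inside (0, 1)")
        if phi <= 0:
            raise DataError("beta precision phi must be positive")
        self.y = y_star
        self.phi = float(phi)
        self.logit_y = np.log(y_star) - np.log1p(-y_star)
        self.log_y = np.log(y_star)
        self.log_1my = np.log1p(-y_star)

    def _mu(self, eta):
        # keep shapes strictly positive
        return np.clip(expit(eta), 1e-12, 1 - 1e-12)

    def logpdf(self, eta):
        mu = self._mu(eta)
        a = mu * self.phi
        b = (1.0 - mu) * self.phi
        return (
            gammaln(self.phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * self.log_y
            + (b - 1.0) * self.log_1my
        )

    def _dmu(self, eta):
        mu = self._mu(eta)
        return self.phi * (self.logit_y - psi(mu * self.phi) + psi((1.0 - mu) * self.phi)), mu

    def d1(self, eta):
        dldmu, mu = self._dmu(eta)
        return dldmu * mu * (1.0 - mu)

    def d2(self, eta):
        dldmu, mu = self._dmu(eta)
        a = mu * self.phi
        b = (1.0 - mu) * self.phi
        d2ldmu2 = -self.phi**2 * (polygamma(1, a) + polygamma(1, b))
        v = mu * (1.0 - mu)
        return d2ldmu2 * v * v + dldmu * v * (1.0 - 2.0 * mu)


class BernoulliZeroObs:
    """Bernoulli density of the zero-decrement indicator, logit link."""

    def __init__(self, is_zero: np.ndarray):
        self.z = np.asarray(is_zero, dtype=float)

    def logpdf(self, eta):
        # z log p + (1-z) log(1-p), numerically via log_expit
        return self.z * log_expit(eta) + (1.0 - self.z) * log_expit(-eta)

    def d1(self, eta):
        return self.z - expit(eta)

    def d2(self, eta):
        p = expit(eta)
        return -p * (1.0 - p)


class AldvmmObs:
    """Mixture-of-censored-normals density on the utility scale.

    Component c has latent mean ``eta + alpha_c`` and SD ``sigma_c``;
    ``eta`` carries the shared covariate effects plus the shared random
    intercept.  Observations at ``u_max`` contribute the upper tail mass
    beyond ``psi1``, observations at ``u_min`` the lower tail mass, and
    interior observations the plain normal density.
    """

    def __init__(
        self,
        u: np.ndarray,
        alphas: np.ndarray,
        sigmas: np.ndarray,
        pis: np.ndarray,
        psi1: float,
        u_min: float = -0.53,
        u_max: float = 1.0,
        boundary_tol: float = 1e-9,
    ):
        self.u = np.asarray(u, dtype=float)
        self.alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
        self.sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
        if np.any(self.sigmas <= 0):
            raise DataError("component SDs must be positive")
        self.pis = np.atleast_1d(np.asarray(pis, dtype=float))
        if np.any(self.pis < 0) or abs(self.pis.sum() - 1.0) > 1e-8:
            raise DataError("class probabilities must be a simplex")
        self.psi1 = float(psi1)
        self.u_min = float(u_min)
        self.u_max = float(u_max)
        self.at_top = self.u >= self.u_max - boundary_tol
        self.at_bottom = self.u <= self.u_min + boundary_tol

    def _component_parts(self, eta):
        """Per-component log f_c and d/d eta log-scale pieces."""
        eta = np.asarray(eta, dtype=float)
        logf = np.empty(eta.shape + (len(self.pis),))
        dlogf = np.empty_like(logf)
        for c, (alpha, sigma) in enumerate(zip(self.alphas, self.sigmas)):
            m = eta + alpha
            # interior normal density
            z = (self.u - m) / sigma
            lf = -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI
            df = z / sigma
            # ceiling mass: P(latent > psi1) = Phi((m - psi1) / sigma)
            zt = (m - self.psi1) / sigma
            lf_top = log_ndtr(zt)
            df_top = _mills(zt) / sigma
            # floor mass: P(latent < u_min) = Phi((u_min - m) / sigma)
            zb = (self.u_min - m) / sigma
            lf_bot = log_ndtr(zb)
            df_bot = -_mills(zb) / sigma
            lf = np.where(self.at_top, lf_top, np.where(self.at_bottom, lf_bot, lf))
            df = np.where(self.at_top, df_top, np.where(self.at_bottom, df_bot, df))
            logf[..., c] = lf
            dlogf[..., c] = df
        return logf, dlogf

    def logpdf(self, eta):
        logf, _ = self._component_parts(eta)
        m = logf + np.log(self.pis)
        mmax = m.max(axis=-1)
        return mmax + np.log(np.exp(m - mmax[..., None]).sum(axis=-1))

    def d1(self, eta):
        logf, dlogf = self._component_parts(eta)
        m = logf + np.log(self.pis)
        mmax = m.max(axis=-1, keepdims=True)
        w = np.exp(m - mmax)
        w /= w.sum(axis=-1, keepdims=True)
        return (w * dlogf).sum(axis=-1)

    def d2(self, eta, h: float = 1e-5):
        # central difference of the analytic score; adequate for the 1-D
        # Newton mode search used with the shared random intercept
        return (self.d1(eta + h) - self.d1(eta - h)) / (2.0 * h)

    def component_means(self, eta):
        """E[u | component c, eta] under the censoring rule, per component.

        Interior partial moment plus boundary masses; used for prediction.
        """
        eta = np.asarray(eta, dtype=float)
        means = np.empty(eta.shape + (len(self.pis),))
        for c, (alpha, sigma) in enumerate(zip(self.alphas, self.sigmas)):
            m = eta + alpha
            zt = (self.psi1 - m) / sigma
            zb = (self.u_min - m) / sigma
            p_top = ndtr(-zt)
            p_bot = ndtr(zb)
            interior = m * (ndtr(zt) - ndtr(zb)) - sigma * (
                np.exp(_norm_logpdf(zt)) - np.exp(_norm_logpdf(zb))
            )
            means[..., c] = p_top * self.u_max + p_bot * self.u_min + interior
        return means
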