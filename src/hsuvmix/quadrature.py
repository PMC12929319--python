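"""Adaptive Gauss–Hermite integration of random effects.

The marginal likelihood of a mixed model multiplies, per patient, the
conditional densities of their repeated questionnaires and integrates
the patient-level random effects b ~ N(0, G) out:

    L_i = integral  prod_j f(y_ij | eta_ij + z_ij' b)  dN(b; 0, G).

For the Gaussian family this has a closed form (see :mod:`hsuvmix.lmm`);
for the beta, two-part and mixture families it is approximated here by
adaptive Gauss–Hermite quadrature: per patient, the integrand's mode is
located by a damped Newton search (vectorised across patients), the grid
is centred at the mode and scaled by the curvature, and a tensor rule
with ``n_nodes`` points per dimension (default 9) is applied.  For a
Gaussian integrand the adaptive rule is exact for any node count.

Random-effect dimension is 1 (random intercept) or 2 (intercept + slope
on the pre-knot time basis).
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss

from .errors import ConfigError, NumericalError

__all__ = ["AghIntegrator"]

_MIN_NODES = 5


def _group_sum(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Sum rows of ``values`` within contiguous patient blocks."""
    return np.add.reduceat(values, starts, axis=0)


def _clip_pd_2x2(c11, c12, c22, eps: float = 1e-6):
    """Force symmetric 2x2 curvature matrices to be positive definite.

    Closed-form eigenvalue floor: conditional log-densities need not be
    concave everywhere, so the observed curvature can lose positive
    definiteness away from the mode.
    """
    tr = c11 + c22
    disc = np.sqrt((c11 - c22) ** 2 + 4.0 * c12**2)
    lam_min = 0.5 * (tr - disc)
    bump = np.maximum(eps - lam_min, 0.0)
    return c11 + bump, c12, c22 + bump


class AghIntegrator:
    """Marginal log-likelihood evaluator for one random-effect block.

    Parameters
    ----------
    Z
        (n_obs, d) random-effect design (columns: 1 and optionally t_pre).
    patient_codes
        Dense patient codes per row; rows must be grouped by patient.
    n_nodes
        Gauss–Hermite nodes per random-effect dimension (>= 5).
    """

    def __init__(self, Z: np.ndarray, patient_codes: np.ndarray, n_nodes: int = 9):
        if n_nodes < _MIN_NODES:
            raise ConfigError(f"quadrature needs >= {_MIN_NODES} nodes, got {n_nodes}")
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.ndim != 2:
            raise ConfigError("Z must be 2-D")
        self.Z = Z
        self.d = Z.shape[1]
        if self.d not in (1, 2):
            raise ConfigError("random-effect dimension must be 1 or 2")
        codes = np.asarray(patient_codes)
        if np.any(np.diff(codes) < 0):
            raise ConfigError("rows must be sorted by patient code")
        new_block = np.r_[True, np.diff(codes) != 0]
        # densify: subsetting rows (e.g. positive decrements only) may
        # leave gaps in the original codes
        self.codes = np.cumsum(new_block) - 1
        self.starts = np.flatnonzero(new_block)
        self.n_pat = len(self.starts)
        t, w = hermgauss(n_nodes)
        if self.d == 1:
            self.nodes = t[:, None]
            self.log_w_star = np.log(w) + t**2
        else:
            tt0, tt1 = np.meshgrid(t, t, indexing="ij")
            self.nodes = np.column_stack([tt0.ravel(), tt1.ravel()])
            ww = np.multiply.outer(w, w).ravel()
            self.log_w_star = np.log(ww) + (self.nodes**2).sum(axis=1)
        # coarse prior-scaled scan grid used to initialise the mode search
        ts, _ = hermgauss(7 if self.d == 1 else 5)
        if self.d == 1:
            self._scan = ts[:, None]
        else:
            s0, s1 = np.meshgrid(ts, ts, indexing="ij")
            self._scan = np.column_stack([s0.ravel(), s1.ravel()])

    # -- mode search ---------------------------------------------------

    def _h(self, family, eta_fix, b, G_inv, log_det_G):
        """Per-patient log integrand h(b) = sum_j log f + log N(b; 0, G)."""
        eta = eta_fix + (self.Z * b[self.codes]).sum(axis=1)
        ll = _group_sum(family.logpdf(eta), self.starts)
        quad = 0.5 * np.einsum("id,de,ie->i", b, G_inv, b)
        prior = -quad - 0.5 * (self.d * np.log(2.0 * np.pi) + log_det_G)
        return ll + prior, eta

    def _h_batch(self, family, eta_fix, B, G_inv, log_det_G):
        """h evaluated at a batch of points: B is (K, n_pat, d) -> (K, n_pat).

        One vectorised density call over all K points keeps the node loop
        out of Python.
        """
        eta = eta_fix[None, :] + np.einsum("jd,kjd->kj", self.Z, B[:, self.codes, :])
        ll = np.add.reduceat(family.logpdf(eta), self.starts, axis=1)
        quad = 0.5 * np.einsum("kid,de,kie->ki", B, G_inv, B)
        prior = -quad - 0.5 * (self.d * np.log(2.0 * np.pi) + log_det_G)
        return ll + prior

    def _scan_start(self, family, eta_fix, G, G_inv, log_det_G):
        """Best point of a prior-scaled grid, per patient.

        The integrand can be multimodal in b (non-log-concave conditional
        densities), so Newton is started from the best of a deterministic
        coarse scan rather than from zero or a previous solution — this
        keeps the marginal likelihood a well-defined function of the
        parameters.
        """
        L = np.linalg.cholesky(G)
        cands = np.vstack([np.zeros((1, self.d)), np.sqrt(2.0) * self._scan @ L.T])
        B = np.broadcast_to(cands[:, None, :], (len(cands), self.n_pat, self.d))
        H = self._h_batch(family, eta_fix, B, G_inv, log_det_G)
        return cands[np.argmax(H, axis=0)]

    def _newton_modes(self, family, eta_fix, G, G_inv, log_det_G, tol=1e-7, max_iter=25):
        b = self._scan_start(family, eta_fix, G, G_inv, log_det_G)
        h, eta = self._h(family, eta_fix, b, G_inv, log_det_G)
        for _ in range(max_iter):
            l1 = family.d1(eta)
            l2 = family.d2(eta)
            grad = _group_sum(self.Z * l1[:, None], self.starts) - b @ G_inv.T
            # curvature C = G_inv - sum l2 z z'; ridge if not positive definite
            if self.d == 1:
                c11 = G_inv[0, 0] - _group_sum(l2 * self.Z[:, 0] ** 2, self.starts)
                c11 = np.maximum(c11, 1e-6)
                step = grad[:, 0] / c11
                step = step[:, None]
                curv = c11[:, None, None]
            else:
                zz11 = _group_sum(l2 * self.Z[:, 0] ** 2, self.starts)
                zz12 = _group_sum(l2 * self.Z[:, 0] * self.Z[:, 1], self.starts)
                zz22 = _group_sum(l2 * self.Z[:, 1] ** 2, self.starts)
                c11, c12, c22 = _clip_pd_2x2(
                    G_inv[0, 0] - zz11, G_inv[0, 1] - zz12, G_inv[1, 1] - zz22
                )
                det = c11 * c22 - c12**2
                step = np.empty_like(grad)
                step[:, 0] = (c22 * grad[:, 0] - c12 * grad[:, 1]) / det
                step[:, 1] = (c11 * grad[:, 1] - c12 * grad[:, 0]) / det
                curv = np.stack(
                    [np.stack([c11, c12], axis=1), np.stack([c12, c22], axis=1)], axis=1
                )
            if np.max(np.abs(grad)) < tol:
                break
            # damped update: halve the step for patients whose h decreased;
            # keep the previous iterate where no improvement is found
            scale = np.ones(self.n_pat)
            for _ in range(8):
                b_try = b + scale[:, None] * step
                h_try, eta_try = self._h(family, eta_fix, b_try, G_inv, log_det_G)
                worse = h_try < h - 1e-12
                if not np.any(worse):
                    break
                scale[worse] *= 0.5
            stuck = h_try < h - 1e-12
            if np.any(stuck):
                b_try[stuck] = b[stuck]
                b = b_try
                h_new, eta = self._h(family, eta_fix, b, G_inv, log_det_G)
            else:
                b, h_new, eta = b_try, h_try, eta_try
            # objective-progress stop: near-flat or oscillating patients
            # no longer justify further Newton work
            if np.max(h_new - h) < 1e-11:
                h = h_new
                break
            h = h_new
        return b, curv

    # -- public API ----------------------------------------------------

    def loglik(self, family, eta_fix: np.ndarray, G: np.ndarray) -> float:
        """Total marginal log-likelihood over patients."""
        return float(self.loglik_per_patient(family, eta_fix, G).sum())

    def loglik_per_patient(self, family, eta_fix: np.ndarray, G: np.ndarray) -> np.ndarray:
        G = np.atleast_2d(np.asarray(G, dtype=float))
        if G.shape != (self.d, self.d):
            raise ConfigError(f"G must be {self.d}x{self.d}")
        sign, log_det_G = np.linalg.slogdet(G)
        if sign <= 0:
            raise NumericalError("random-effect covariance is not positive definite")
        G_inv = np.linalg.inv(G)
        modes, curv = self._newton_modes(family, eta_fix, G, G_inv, log_det_G)
        # Cholesky of curv^{-1}, closed form per patient
        if self.d == 1:
            L = 1.0 / np.sqrt(curv[:, :, 0])  # (n_pat, 1)
            log_det_L = np.log(L[:, 0])
            shifts = np.sqrt(2.0) * L[:, 0:1, None] * self.nodes.T[None]  # (n_pat,1,K)
        else:
            c11 = curv[:, 0, 0]
            c12 = curv[:, 0, 1]
            c22 = curv[:, 1, 1]
            det = c11 * c22 - c12**2
            a11 = c22 / det
            a12 = -c12 / det
            a22 = c11 / det
            L11 = np.sqrt(a11)
            L21 = a12 / L11
            L22 = np.sqrt(np.maximum(a22 - L21**2, 1e-300))
            log_det_L = np.log(L11) + np.log(L22)
            K = self.nodes.shape[0]
            shifts = np.empty((self.n_pat, 2, K))
            shifts[:, 0, :] = np.sqrt(2.0) * L11[:, None] * self.nodes[:, 0][None, :]
            shifts[:, 1, :] = np.sqrt(2.0) * (
                L21[:, None] * self.nodes[:, 0][None, :]
                + L22[:, None] * self.nodes[:, 1][None, :]
            )
        K = self.nodes.shape[0]
        B = modes[None, :, :] + np.moveaxis(shifts, 2, 0)  # (K, n_pat, d)
        H = self._h_batch(family, eta_fix, B, G_inv, log_det_G).T  # (n_pat, K)
        M = H + self.log_w_star[None, :]
        m_max = M.max(axis=1)
        ll = (
            m_max
            + np.log(np.exp(M - m_max[:, None]).sum(axis=1))
            + 0.5 * self.d * np.log(2.0)
            + log_det_L
        )
        if not np.all(np.isfinite(ll)):
            raise NumericalError("non-finite marginal likelihood contribution")
        return ll
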