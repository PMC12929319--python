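"""Transforms between the utility scale and the bounded decrement scale.

EQ-5D-3L utilities from the French tariff live in [u_min, u_max] =
[-0.53, 1.00].  Beta-family models work on the rescaled *decrement*

    y = (u_max - u) / (u_max - u_min)  in [0, 1],

i.e. the shortfall from full health, so that y = 0 is full health and
y = 1 the worst attainable state.  Because a beta density has no mass at
the boundaries, observed decrements are *compressed* strictly inside
(0, 1) with

    y* = (y * (N - 1) + 0.5) / N,

where N is the number of observations being transformed.  Predictions
on the decrement scale are mapped back to utilities with the inverse of
the rescaling.

Follow-up time t (years since transplantation) enters the models through
a piecewise-linear basis with a knot at 1 year: t_pre = min(t, knot) and
t_post = max(t - knot, 0), capturing a fast early evolution and a slower
long-term trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "TransformSpec",
    "rescale_to_decrement",
    "compress",
    "back_transform",
    "time_basis",
]

#: Default bounds of the French EQ-5D-3L value set.
U_MIN_DEFAULT = -0.53
U_MAX_DEFAULT = 1.00


@dataclass(frozen=True)
class TransformSpec:
    """Bounds of the utility scale and the compression sample size.

    Parameters
    ----------
    u_min, u_max
        Attainable utility bounds (value-set dependent); defaults are the
        French EQ-5D-3L tariff bounds -0.53 and 1.00.
    n_obs
        Total number of observations N used by :func:`compress`.
    """

    u_min: float = U_MIN_DEFAULT
    u_max: float = U_MAX_DEFAULT
    n_obs: int = 2

    def __post_init__(self) -> None:
        if not self.u_min < self.u_max:
            raise ConfigError(f"u_min ({self.u_min}) must be < u_max ({self.u_max})")
        if self.n_obs < 2:
            raise ConfigError(f"compression requires N >= 2, got {self.n_obs}")

    @property
    def span(self) -> float:
        return self.u_max - self.u_min


def rescale_to_decrement(u, spec: TransformSpec = TransformSpec()):
    """Map utilities u in [u_min, u_max] to decrements y in [0, 1].

    y = (u_max - u) / (u_max - u_min); y = 0 iff u = u_max (full health).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < spec.u_min - 1e-12) or np.any(u > spec.u_max + 1e-12):
        raise DataError(
            f"utility outside [{spec.u_min}, {spec.u_max}]: "
            f"range [{u.min()}, {u.max()}]"
        )
    y = (spec.u_max - u) / spec.span
    return np.clip(y, 0.0, 1.0)[()] if y.ndim == 0 else np.clip(y, 0.0, 1.0)


def compress(y, spec: TransformSpec):
    """Pull decrements in [0, 1] strictly inside (0, 1).

    y* = (y (N - 1) + 0.5) / N with N = ``spec.n_obs``; order-preserving,
    with fixed point 0.5.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise DataError("decrement outside [0, 1]")
    n = spec.n_obs
    return (y * (n - 1) + 0.5) / n


def back_transform(y_hat, spec: TransformSpec = TransformSpec()):
    """Map predicted decrements in [0, 1] back to the utility scale.

    Exact inverse of :func:`rescale_to_decrement`:
    u_hat = u_max - y_hat (u_max - u_min).
    """
    y_hat = np.asarray(y_hat, dtype=float)
    if np.any(y_hat < -1e-12) or np.any(y_hat > 1 + 1e-12):
        raise DataError("predicted decrement outside [0, 1]")
    return spec.u_max - y_hat * spec.span


def time_basis(t, knot: float = 1.0):
    """Split time since transplantation into pre- and post-knot pieces.

    Returns ``(t_pre, t_post)`` with t_pre = min(t, knot) and
    t_post = max(t - knot, 0), so t_pre + t_post = t and the basis is
    continuous at the knot (default 1 year).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DataError("time since transplantation must be >= 0")
    t_pre = np.minimum(t, knot)
    t_post = np.maximum(t - knot, 0.0)
    return t_pre, t_post
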