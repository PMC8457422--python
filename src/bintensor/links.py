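"""Link families for the Bernoulli tensor model.

Each family maps a latent value theta to a success probability
``f(theta) = P(eps >= -theta)`` where ``eps`` is the latent noise: logistic
noise (logistic link), Gaussian noise (probit link), Laplace noise (Laplacian
link), all with a scale parameter ``sigma``.  Every family satisfies
``f(-theta) = 1 - f(theta)``, is strictly increasing, and strictly
log-concave, which is what makes the per-row GLM subproblems concave.

Besides the link value/derivative, the module exposes the overflow-safe
``log f`` together with its first derivative (the per-entry score scale) and
its negative second derivative (the per-entry Newton curvature), and the
steepness/convexity diagnostics ``L_alpha``/``gamma_alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_ndtr, ndtr

__all__ = [
    "LinkSpec",
    "DiagnosticValue",
    "link_value",
    "link_derivative",
    "log_link",
    "dlog_link",
    "log_link_curvature",
    "steepness_L",
    "convexity_gamma",
]

_FAMILIES = ("logistic", "probit", "laplacian")

# Below this |theta| the Laplacian curvature uses the average of its left and
# right limits (the second derivative is undefined at 0).
_LAPLACE_KINK_TOL = 1e-8

_LOG_HALF = float(np.log(0.5))
_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class LinkSpec:
    """Link family plus scale ``sigma > 0`` of the latent noise."""

    family: str
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown link family {self.family!r}; choose from {_FAMILIES}"
            )
        if not self.sigma > 0:
            raise ValueError(f"link scale sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class DiagnosticValue:
    """A steepness/convexity constant; ``is_bound`` marks a printed bound
    rather than the exact sup/inf."""

    value: float
    is_bound: bool


def _z(theta, link: LinkSpec) -> np.ndarray:
    return np.asarray(theta, dtype=float) / link.sigma


def link_value(theta, link: LinkSpec):
    """Success probability ``f(theta)``, strictly inside (0, 1) for finite theta."""
    z = _z(theta, link)
    if link.family == "logistic":
        return expit(z)
    if link.family == "probit":
        return ndtr(z)
    # laplacian
    return np.where(
        z < 0,
        0.5 * np.exp(np.minimum(z, 0.0)),
        1.0 - 0.5 * np.exp(-np.maximum(z, 0.0)),
    )


def link_derivative(theta, link: LinkSpec):
    """Density ``f'(theta)`` of the latent noise; symmetric and unimodal.

    The Laplacian derivative at 0 is taken as the two-sided limit 1/(2 sigma).
    """
    z = _z(theta, link)
    s = link.sigma
    if link.family == "logistic":
        p = expit(z)
        return p * (1.0 - p) / s
    if link.family == "probit":
        return np.exp(-0.5 * z**2) / (_SQRT_2PI * s)
    return 0.5 * np.exp(-np.abs(z)) / s


def log_link(theta, link: LinkSpec):
    """Overflow-safe ``log f(theta)``; finite for any finite theta."""
    z = _z(theta, link)
    if link.family == "logistic":
        return -np.logaddexp(0.0, -z)
    if link.family == "probit":
        return log_ndtr(z)
    return np.where(
        z < 0,
        _LOG_HALF + z,
        np.log1p(-0.5 * np.exp(-np.maximum(z, 0.0))),
    )


def dlog_link(theta, link: LinkSpec):
    """First derivative of ``log f``; equals ``f'(theta)/f(theta)``."""
    z = _z(theta, link)
    s = link.sigma
    if link.family == "logistic":
        return expit(-z) / s
    if link.family == "probit":
        # Mills-ratio form exp(log phi - log Phi), stable far into both tails.
        log_phi = -0.5 * z**2 - np.log(_SQRT_2PI)
        return np.exp(log_phi - log_ndtr(z)) / s
    e = np.exp(-np.maximum(z, 0.0))
    return np.where(z < 0, 1.0 / s, e / (s * (2.0 - e)))


def log_link_curvature(theta, link: LinkSpec):
    """Negative second derivative of ``log f``; nonnegative by log-concavity.

    This is the per-entry Newton weight of the row GLMs.  The Laplacian link
    is log-linear for theta < 0 (curvature 0) and the kink at 0 uses the
    average of the two one-sided limits.
    """
    z = _z(theta, link)
    s2 = link.sigma**2
    if link.family == "logistic":
        p = expit(z)
        return p * (1.0 - p) / s2
    if link.family == "probit":
        lam = dlog_link(theta, link) * link.sigma  # phi/Phi at z
        return lam * (lam + z) / s2
    e = np.exp(-np.maximum(z, 0.0))
    right = 0.5 * e / (s2 * (1.0 - 0.5 * e) ** 2)
    out = np.where(z < 0, 0.0, right)
    kink = np.abs(z) < _LAPLACE_KINK_TOL / link.sigma
    return np.where(kink, 1.0 / s2, out)


def steepness_L(alpha: float, link: LinkSpec) -> DiagnosticValue:
    """Steepness constant ``L_alpha = sup_{|theta|<=alpha} f'/(f(1-f))``.

    Exact (and independent of alpha) for the logistic family; for probit and
    Laplacian the printed upper bounds are returned with ``is_bound=True``.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    s = link.sigma
    if link.family == "logistic":
        return DiagnosticValue(1.0 / s, False)
    if link.family == "probit":
        return DiagnosticValue(2.0 / s * (alpha / s + 1.0), True)
    return DiagnosticValue(2.0 / s, True)


def convexity_gamma(alpha: float, link: LinkSpec) -> DiagnosticValue:
    """Convexity constant ``gamma_alpha = inf_{|theta|<=alpha} (f'^2/f^2 - f''/f)``.

    Exact for the logistic family; printed lower bounds otherwise.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    s = link.sigma
    if link.family == "logistic":
        e = np.exp(alpha / s)
        return DiagnosticValue(float(e / ((1.0 + e) ** 2 * s**2)), False)
    if link.family == "probit":
        val = (alpha / s + 1.0 / 6.0) * np.exp(-(alpha**2) / s**2) / (2.0 * np.pi * s**2)
        return DiagnosticValue(float(val), True)
    return DiagnosticValue(float(np.exp(-alpha / s) / (2.0 * s**2)), True)
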