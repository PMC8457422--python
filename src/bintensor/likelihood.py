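"""Bernoulli log-likelihood, entrywise score, and the per-row GLM solver.

With the sign coding ``s = 2y - 1`` the log-likelihood of a single entry is
``log f(s * theta)`` by symmetry of the link, so the whole objective is a sum
of log-concave terms and each row subproblem of the alternating algorithm is
a concave GLM fit.  The solver is a damped Newton (IRLS-style) ascent with a
ridge on the curvature and per-row step-halving; it never decreases the
objective relative to its starting point, and a hard box on the coefficients
keeps perfect-separation rows finite when the signal bound alpha is infinite.

``_newton_rows`` solves many rows that share one design matrix in a single
batched pass; :func:`glm_fit_row` is the single-problem surface over it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .links import LinkSpec, dlog_link, log_link, log_link_curvature
from .tensor_core import BinaryTensor

__all__ = ["GLMProblem", "RowFit", "log_likelihood", "score_entries", "glm_fit_row"]

#: default damping ridge on the Newton curvature
DEFAULT_RIDGE = 1e-8
#: default gradient-norm convergence tolerance
DEFAULT_TOL = 1e-8
#: default Newton iteration cap
DEFAULT_MAX_ITER = 50
#: maximum number of step halvings per Newton step
MAX_HALVINGS = 30
#: hard cap on |beta|_inf per row; only active under (near-)separation
DEFAULT_COEF_CAP = 1e3


@dataclass
class GLMProblem:
    """One Bernoulli GLM: binary response, n x R design, optional observed flags."""

    response: np.ndarray
    design: np.ndarray
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response)
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2 or self.design.shape[0] != self.response.shape[0]:
            raise ValueError("design must be n x R with n matching the response")
        if not np.isfinite(self.design).all():
            raise ValueError("design contains non-finite values")
        if not np.isin(np.unique(self.response), (0, 1)).all():
            raise ValueError("response entries must be 0 or 1")
        if self.observed is not None:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != self.response.shape:
                raise ValueError("observed flags must match the response length")
            if not self.observed.any():
                raise ValueError("at least one response must be observed")


@dataclass
class RowFit:
    """Result of one row GLM: coefficients, convergence flag, iterations."""

    coef: np.ndarray
    converged: bool
    n_iter: int


def log_likelihood(Y: BinaryTensor, theta: np.ndarray, link: LinkSpec) -> float:
    """Sum of ``log f((2y - 1) theta)`` over the observed entries; always <= 0."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != Y.dims:
        raise ValueError(f"theta shape {theta.shape} does not match Y dims {Y.dims}")
    s = 2.0 * Y.data - 1.0
    terms = log_link(s * theta, link)
    if Y.mask is not None:
        return float(terms[Y.mask].sum())
    return float(terms.sum())


def score_entries(Y: BinaryTensor, theta: np.ndarray, link: LinkSpec) -> np.ndarray:
    """Entrywise derivative of the log-likelihood in theta.

    ``f'(theta)/f(theta)`` where y = 1 and ``-f'(theta)/(1 - f(theta))`` where
    y = 0; zero at missing entries.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != Y.dims:
        raise ValueError(f"theta shape {theta.shape} does not match Y dims {Y.dims}")
    s = 2.0 * Y.data - 1.0
    out = s * dlog_link(s * theta, link)
    if Y.mask is not None:
        out = np.where(Y.mask, out, 0.0)
    return out


def _row_objectives(S: np.ndarray, eta: np.ndarray, link: LinkSpec,
                    obs: np.ndarray | None) -> np.ndarray:
    terms = log_link(S * eta, link)
    if obs is not None:
        terms = np.where(obs, terms, 0.0)
    return terms.sum(axis=1)


def _newton_rows(
    S: np.ndarray,
    X: np.ndarray,
    B0: np.ndarray,
    link: LinkSpec,
    obs: np.ndarray | None = None,
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    coef_cap: float = DEFAULT_COEF_CAP,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Damped Newton ascent for ``m`` rows sharing the design ``X``.

    Parameters
    ----------
    S : (m, n) array of signs 2y - 1.
    X : (n, R) shared design matrix.
    B0 : (m, R) starting coefficients.
    obs : optional (m, n) boolean observed flags.

    Returns ``(B, converged_rows, n_iter)``.  Each accepted step does not
    decrease its row objective; rows whose halved steps all fail keep their
    previous iterate, so the final objective is >= the objective at ``B0``.
    """
    m, n = S.shape
    R = X.shape[1]
    B = np.array(B0, dtype=float, copy=True)
    if R == 0:
        return B, np.ones(m, dtype=bool), 0
    eta = B @ X.T
    obj = _row_objectives(S, eta, link, obs)
    converged = np.zeros(m, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        z = S * eta
        g = S * dlog_link(z, link)
        w = log_link_curvature(z, link)
        if obs is not None:
            g = np.where(obs, g, 0.0)
            w = np.where(obs, w, 0.0)
        grad = g @ X
        converged = np.abs(grad).max(axis=1) < tol
        active = ~converged
        if not active.any():
            break
        H = np.matmul((w[:, :, None] * X[None, :, :]).transpose(0, 2, 1),
                      X[None, :, :])
        # damping scaled to each row's curvature so it survives ill-scaled
        # designs (collapsed components make Khatri-Rao columns proportional
        # and H rank-deficient at any absolute ridge)
        diag_scale = np.maximum(1.0, np.trace(H, axis1=1, axis2=2) / R)
        H += (ridge * diag_scale)[:, None, None] * np.eye(R)[None, :, :]
        try:
            delta = np.linalg.solve(H[active], grad[active][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            delta = np.stack([
                np.linalg.lstsq(H_j, g_j, rcond=None)[0]
                for H_j, g_j in zip(H[active], grad[active])
            ])
        act_idx = np.flatnonzero(active)
        step = np.ones(act_idx.size)
        remaining = np.ones(act_idx.size, dtype=bool)
        for _ in range(MAX_HALVINGS + 1):
            if not remaining.any():
                break
            rows = act_idx[remaining]
            cand = B[rows] + step[remaining, None] * delta[remaining]
            # scale offending rows back into the coefficient box
            mx = np.abs(cand).max(axis=1)
            over = mx > coef_cap
            if over.any():
                cand[over] *= (coef_cap / mx[over])[:, None]
            eta_c = cand @ X.T
            obj_c = _row_objectives(S[rows], eta_c, link,
                                    None if obs is None else obs[rows])
            ok = obj_c >= obj[rows]
            if ok.any():
                accepted = rows[ok]
                B[accepted] = cand[ok]
                eta[accepted] = eta_c[ok]
                obj[accepted] = obj_c[ok]
            rem_rows = np.flatnonzero(remaining)
            remaining[rem_rows[ok]] = False
            step[remaining] *= 0.5
    return B, converged, it


def glm_fit_row(
    problem: GLMProblem,
    link: LinkSpec,
    init: np.ndarray | None = None,
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    coef_cap: float = DEFAULT_COEF_CAP,
) -> RowFit:
    """Fit one Bernoulli GLM by damped Newton ascent.

    Non-convergence is reported through ``RowFit.converged``, never raised:
    under perfect separation the coefficients run to the box ``coef_cap`` and
    the gradient cannot vanish, which is expected behaviour when the signal
    bound alpha is infinite.
    """
    X = problem.design
    R = X.shape[1]
    if R > 0 and not (X != 0).any(axis=0).all():
        raise ValueError("design has an all-zero column")
    if init is None:
        init = np.zeros(R)
    init = np.asarray(init, dtype=float)
    if init.shape != (R,):
        raise ValueError(f"init must have shape ({R},)")
    S = (2.0 * problem.response - 1.0)[None, :]
    obs = None if problem.observed is None else problem.observed[None, :]
    B, conv, n_iter = _newton_rows(
        S, X, init[None, :], link, obs=obs, ridge=ridge,
        max_iter=max_iter, tol=tol, coef_cap=coef_cap,
    )
    return RowFit(coef=B[0], converged=bool(conv[0]), n_iter=n_iter)
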