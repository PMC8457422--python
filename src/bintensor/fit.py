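"""Alternating block-GLM maximization of the constrained Bernoulli likelihood.

One iteration sweeps the modes in ascending order, replacing each factor
matrix by the row-wise GLM solutions with the Khatri-Rao product of the other
modes as the shared design, then applies a single global line search between
the pre-sweep and post-sweep factor collections (restricted to blends whose
reconstruction satisfies the max-norm bound alpha), and finally renormalizes
the factors.  Because the line-search grid contains gamma = 1 (the previous
iterate) and each row GLM never decreases its own objective, the recorded
log-likelihood trace is non-decreasing by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .likelihood import (
    DEFAULT_COEF_CAP,
    DEFAULT_RIDGE,
    _newton_rows,
    log_likelihood,
)
from .links import LinkSpec
from .tensor_core import (
    BinaryTensor,
    CPFactors,
    cp_reconstruct,
    khatri_rao,
    normalize_factors,
    unfold,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "initialize_factors",
    "update_block",
    "line_search",
    "decompose",
    "multi_start_decompose",
    "iterations_to_relative_change",
]

#: inner GLM Newton iterations per block update; the outer sweeps provide
#: further refinement, so the rows need not be solved to death each time
GLM_MAX_ITER = 25
GLM_TOL = 1e-8
#: golden-section refinement iterations around the best line-search grid point
_GOLDEN_ITER = 12
_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class FitOptions:
    """Settings of the alternating algorithm.

    ``alpha`` is the max-norm signal bound (``inf`` poses no magnitude
    constraint, the setting used in the method comparisons); ``tol`` is the
    relative objective-change stopping threshold; ``n_starts`` consecutive
    seeds are used by :func:`multi_start_decompose`.
    """

    rank: int
    alpha: float = math.inf
    tol: float = 1e-4
    max_iter: int = 100
    n_starts: int = 5
    seed: int = 0
    line_search_grid_size: int = 21
    glm_ridge: float = DEFAULT_RIDGE
    coef_cap: float = DEFAULT_COEF_CAP

    def __post_init__(self) -> None:
        if self.rank < 0:
            raise ValueError("rank must be nonnegative")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be at least 1")
        if self.line_search_grid_size < 2:
            raise ValueError("line-search grid needs at least 2 points")


@dataclass
class FitResult:
    """Converged factors, reconstruction, and the per-iteration objective trace."""

    factors: CPFactors
    theta_hat: np.ndarray
    loglik_trace: list[float]
    iterations: int
    converged: bool
    seed_used: int
    start_objectives: list[float] | None = None

    @property
    def objective(self) -> float:
        return self.loglik_trace[-1]


def initialize_factors(dims, rank: int, seed: int) -> CPFactors:
    """Standard Gaussian factor entries, normalized; deterministic given seed."""
    if rank < 1:
        raise ValueError("initialization requires rank >= 1")
    rng = np.random.default_rng(seed)
    mats = [rng.standard_normal((d, rank)) for d in dims]
    return normalize_factors(CPFactors(mats))


def update_block(
    Y: BinaryTensor,
    factors: CPFactors,
    mode: int,
    link: LinkSpec,
    mask: np.ndarray | None = None,
    init: str = "warm",
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = GLM_MAX_ITER,
    tol: float = GLM_TOL,
    coef_cap: float = DEFAULT_COEF_CAP,
) -> np.ndarray:
    """Solve the d_k row GLMs of mode ``mode`` and return the new factor matrix.

    The design is the Khatri-Rao product of the other modes in ascending
    order; row ``j`` regresses the vectorized slice ``Y(:, j, :)`` on it.
    ``init`` is ``"warm"`` (start Newton at the current rows) or ``"zero"``.
    Missing entries are dropped row-wise.  The block objective never
    decreases.
    """
    if not 0 <= mode < factors.order:
        raise ValueError(f"mode {mode} out of range")
    others = [f for k, f in enumerate(factors.factors) if k != mode]
    X = khatri_rao(others)
    S = 2.0 * unfold(Y.data, mode).astype(float) - 1.0
    obs = None
    if mask is not None:
        obs = unfold(mask, mode)
        if not obs.any(axis=1).all():
            raise ValueError(
                f"completely missing subtensor in mode {mode}: cannot update block"
            )
    B0 = factors.factors[mode] if init == "warm" else np.zeros_like(
        factors.factors[mode]
    )
    B, _, _ = _newton_rows(
        S, X, B0, link, obs=obs, ridge=ridge, max_iter=max_iter, tol=tol,
        coef_cap=coef_cap,
    )
    return B


def _blend(prev: CPFactors, new: CPFactors, gamma: float) -> CPFactors:
    return CPFactors(
        [gamma * a + (1.0 - gamma) * b
         for a, b in zip(prev.factors, new.factors)]
    )


def line_search(
    factors_prev: CPFactors,
    factors_new: CPFactors,
    Y: BinaryTensor,
    link: LinkSpec,
    alpha: float = math.inf,
    grid_size: int = 21,
) -> tuple[float, CPFactors, float]:
    """Global line search on ``gamma * A_prev + (1 - gamma) * A_new``.

    Maximizes the log-likelihood over a uniform grid on [0, 1] restricted to
    feasible blends (``max |theta| <= alpha``), then refines once by
    golden-section around the best grid point; the refined point is kept only
    if it strictly improves.  Returns ``(gamma, blended factors, objective)``.
    If no grid point is feasible, returns the previous iterate with a warning.
    """

    def objective(gamma: float) -> tuple[float, CPFactors]:
        fac = _blend(factors_prev, factors_new, gamma)
        theta = cp_reconstruct(fac)
        if np.isfinite(alpha) and np.abs(theta).max() > alpha:
            return -math.inf, fac
        return log_likelihood(Y, theta, link), fac

    grid = np.linspace(0.0, 1.0, grid_size)
    values = []
    blends = []
    for g in grid:
        val, fac = objective(g)
        values.append(val)
        blends.append(fac)
    values = np.asarray(values)
    if not np.isfinite(values).any():
        warnings.warn(
            "no feasible point on the line-search grid; keeping previous iterate",
            RuntimeWarning,
            stacklevel=2,
        )
        prev_obj = log_likelihood(Y, cp_reconstruct(factors_prev), link)
        return 1.0, factors_prev, prev_obj
    best = int(values.argmax())
    best_gamma, best_val, best_fac = float(grid[best]), float(values[best]), blends[best]
    if best in (0, grid_size - 1):
        # endpoint maximum: the grid already brackets it; refinement toward
        # the interior could only move away from it
        return best_gamma, best_fac, best_val

    # one golden-section refinement inside the bracket around the best point
    a, b = float(grid[best - 1]), float(grid[best + 1])
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fac_c = objective(c)
    fd, fac_d = objective(d)
    for _ in range(_GOLDEN_ITER):
        if fc >= fd:
            b, d, fd, fac_d = d, c, fc, fac_c
            c = b - _INVPHI * (b - a)
            fc, fac_c = objective(c)
        else:
            a, c, fc, fac_c = c, d, fd, fac_d
            d = a + _INVPHI * (b - a)
            fd, fac_d = objective(d)
    for g, val, fac in ((c, fc, fac_c), (d, fd, fac_d)):
        if val > best_val:
            best_gamma, best_val, best_fac = float(g), float(val), fac
    return best_gamma, best_fac, best_val


def decompose(Y: BinaryTensor, link: LinkSpec, opts: FitOptions) -> FitResult:
    """Run the alternating algorithm from one random initialization.

    Stops when the relative objective change drops below ``opts.tol`` or
    after ``opts.max_iter`` sweeps (``converged=False`` in that case, result
    still returned).  The trace is non-decreasing and the run is
    deterministic given the seed.
    """
    mask = Y.mask
    if opts.rank == 0:
        theta = np.zeros(Y.dims)
        ll = log_likelihood(Y, theta, link)
        return FitResult(
            factors=CPFactors([np.zeros((d, 0)) for d in Y.dims]),
            theta_hat=theta,
            loglik_trace=[ll],
            iterations=0,
            converged=True,
            seed_used=opts.seed,
        )
    factors = initialize_factors(Y.dims, opts.rank, opts.seed)
    ll = log_likelihood(Y, cp_reconstruct(factors), link)
    trace = [ll]
    converged = False
    iterations = 0
    for t in range(opts.max_iter):
        prev = factors.copy()
        work = factors
        for k in range(work.order):
            new_mat = update_block(
                Y, work, k, link, mask=mask,
                init="zero" if t == 0 else "warm",
                ridge=opts.glm_ridge, coef_cap=opts.coef_cap,
            )
            work = CPFactors(
                [new_mat if j == k else f for j, f in enumerate(work.factors)]
            )
        _, blended, ll_new = line_search(
            prev, work, Y, link, alpha=opts.alpha,
            grid_size=opts.line_search_grid_size,
        )
        factors = normalize_factors(blended)
        trace.append(ll_new)
        iterations = t + 1
        if abs(ll_new - ll) < opts.tol * abs(ll):
            converged = True
            break
        ll = ll_new
    theta = cp_reconstruct(factors)
    return FitResult(
        factors=factors,
        theta_hat=theta,
        loglik_trace=trace,
        iterations=iterations,
        converged=converged,
        seed_used=opts.seed,
    )


def multi_start_decompose(Y: BinaryTensor, link: LinkSpec,
                          opts: FitOptions) -> FitResult:
    """Run :func:`decompose` from seeds ``seed, seed+1, ...`` and keep the best.

    The returned result carries the final objectives of every start, so the
    spread across initializations can be inspected.
    """
    best: FitResult | None = None
    finals: list[float] = []
    for i in range(opts.n_starts):
        res = decompose(Y, link, replace(opts, seed=opts.seed + i))
        finals.append(res.objective)
        if best is None or res.objective > best.objective:
            best = res
    assert best is not None
    best.start_objectives = finals
    return best


def iterations_to_relative_change(trace, rel_tol: float = 0.03) -> int | None:
    """First sweep index t >= 1 with |L_t - L_{t-1}| / |L_{t-1}| < rel_tol."""
    for t in range(1, len(trace)):
        if abs(trace[t] - trace[t - 1]) < rel_tol * abs(trace[t - 1]):
            return t
    return None
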