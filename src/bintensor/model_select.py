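"""BIC rank selection, completion prediction, and evaluation metrics."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import roc_auc_score

from .fit import FitOptions, FitResult, multi_start_decompose
from .links import LinkSpec, link_value
from .tensor_core import BinaryTensor, effective_num_params

__all__ = [
    "RankSelectionReport",
    "bic",
    "select_rank",
    "predict_probabilities",
    "loss_frobenius",
    "relative_loss",
    "rmse_prob",
    "mer",
    "completion_holdout",
]


@dataclass
class RankSelectionReport:
    """Per-rank BIC/log-likelihood values and the BIC-minimizing rank.

    Ties break toward the smallest rank.
    """

    grid: list[int]
    bic_values: list[float]
    loglik_values: list[float]
    chosen_rank: int
    fits: list[FitResult] | None = None


def bic(loglik: float, dims, rank: int, n_obs: int | None = None) -> float:
    """``-2 L + p_e(R) log(n)`` with ``n`` the number of observed entries.

    For fully observed tensors ``n = prod(dims)``; under missing data the
    observed count replaces it (standard effective sample size).
    """
    if n_obs is None:
        n_obs = int(np.prod(dims))
    return -2.0 * loglik + effective_num_params(dims, rank) * math.log(n_obs)


def select_rank(Y: BinaryTensor, link: LinkSpec, grid, fit_opts: FitOptions,
                keep_fits: bool = False) -> RankSelectionReport:
    """Fit every candidate rank via multi-start and pick the BIC minimizer.

    Every rank is fitted from the same base seed so results for nested grids
    are comparable run to run.
    """
    grid = [int(r) for r in grid]
    if not grid:
        raise ValueError("rank grid must be non-empty")
    if any(r < 0 for r in grid):
        raise ValueError("candidate ranks must be nonnegative")
    n_obs = Y.n_observed
    logliks, bics, fits = [], [], []
    for r in grid:
        res = multi_start_decompose(Y, link, replace(fit_opts, rank=r))
        logliks.append(res.objective)
        bics.append(bic(res.objective, Y.dims, r, n_obs=n_obs))
        fits.append(res)
    order = sorted(range(len(grid)), key=lambda i: (bics[i], grid[i]))
    chosen = grid[order[0]]
    return RankSelectionReport(
        grid=grid,
        bic_values=bics,
        loglik_values=logliks,
        chosen_rank=chosen,
        fits=fits if keep_fits else None,
    )


def predict_probabilities(fit: FitResult, link: LinkSpec) -> np.ndarray:
    """Entrywise ``f(theta_hat)``, strictly inside (0, 1).

    ``f`` maps finite latents into the open unit interval, but under strong
    signal the floating-point value can round to exactly 0 or 1; such entries
    are clamped to the nearest representable interior value so downstream
    consumers can rely on the open-interval contract.
    """
    tiny = np.finfo(float).tiny
    eps = np.finfo(float).epsneg
    return np.clip(link_value(fit.theta_hat, link), tiny, 1.0 - eps)


def loss_frobenius(theta_hat: np.ndarray, theta_true: np.ndarray) -> float:
    """Root-mean-square entrywise deviation ``|T1 - T2|_F / sqrt(prod d)``."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    if theta_hat.shape != theta_true.shape:
        raise ValueError("shape mismatch")
    return float(np.linalg.norm(theta_hat - theta_true) / math.sqrt(theta_true.size))


def relative_loss(theta_hat: np.ndarray, theta_true: np.ndarray) -> float:
    """``|T1 - T2|_F / |T2|_F``; undefined for a zero-norm truth."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    if theta_hat.shape != theta_true.shape:
        raise ValueError("shape mismatch")
    denom = np.linalg.norm(theta_true)
    if denom == 0.0:
        raise ValueError("relative loss undefined for a zero-norm truth tensor")
    return float(np.linalg.norm(theta_hat - theta_true) / denom)


def rmse_prob(p_hat: np.ndarray, p_true: np.ndarray) -> float:
    """RMSE between two probability tensors."""
    return loss_frobenius(p_hat, p_true)


def mer(p_hat: np.ndarray, p_true: np.ndarray) -> float:
    """Misclassification rate between the tensors thresholded at 1/2."""
    p_hat = np.asarray(p_hat, dtype=float)
    p_true = np.asarray(p_true, dtype=float)
    if p_hat.shape != p_true.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((p_hat >= 0.5) != (p_true >= 0.5)))


def completion_holdout(
    Y: BinaryTensor,
    link: LinkSpec,
    fit_opts: FitOptions,
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> dict:
    """Hold out a stratified fraction of entries, fit on the rest, score.

    The 1-entries and 0-entries are split separately so the held-out set
    preserves the observed density.  Returns AUC (rank statistic of the
    predicted probabilities against the held-out labels) and the RMSE of the
    predictions against those labels.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    base_mask = Y.mask if Y.mask is not None else np.ones(Y.dims, dtype=bool)
    train_mask = base_mask.copy()
    flat = Y.data.ravel()
    obs_flat = base_mask.ravel()
    test_idx = []
    for value in (0, 1):
        pool = np.flatnonzero(obs_flat & (flat == value))
        n_hold = int(round(holdout_fraction * pool.size))
        chosen = rng.choice(pool, size=n_hold, replace=False)
        test_idx.append(chosen)
    test_idx = np.concatenate(test_idx)
    train_mask.ravel()[test_idx] = False
    labels = flat[test_idx]
    if labels.size == 0 or labels.min() == labels.max():
        raise ValueError("degenerate holdout: AUC needs both classes present")
    Y_train = BinaryTensor(Y.data.copy(), train_mask)  # raises if a slice empties
    res = multi_start_decompose(Y_train, link, fit_opts)
    probs = predict_probabilities(res, link).ravel()[test_idx]
    auc = float(roc_auc_score(labels, probs))
    rmse = float(np.sqrt(np.mean((probs - labels) ** 2)))
    return {"auc": auc, "rmse": rmse, "n_heldout": int(labels.size), "fit": res}
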