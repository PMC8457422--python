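"""Seeded generators for the three binary-tensor data models used in testing.

* CP-threshold model: a rank-R signal tensor with Uniform[-1, 1] factor
  entries, rescaled to unit max-norm, quantized through additive noise
  (``Y = 1{Theta + E >= 0}``) — equivalent to the Bernoulli link model with
  the link matched to the noise family.
* Stochastic multi-way block model: a block-constant latent tensor (three
  block-mean sub-models) pushed through the probit to a probability tensor.
* Boolean OR-AND model: binary factors with Beta-distributed probabilities,
  logical OR over components of the AND of the factor bits, plus flip noise.

All generators are byte-reproducible given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .links import LinkSpec
from .tensor_core import BinaryTensor, CPFactors, cp_reconstruct

__all__ = [
    "SimOutput",
    "simulate_cp_threshold",
    "simulate_multiway_block",
    "simulate_boolean",
    "boolean_mean_probability",
    "matched_link",
    "matched_logistic_link",
]

#: noise family of the threshold model -> equivalent Bernoulli link family
NOISE_TO_LINK = {"gaussian": "probit", "logistic": "logistic", "laplace": "laplacian"}

#: standard deviation of each noise family at unit scale parameter
_NOISE_SD = {"gaussian": 1.0, "logistic": math.pi / math.sqrt(3.0),
             "laplace": math.sqrt(2.0)}


@dataclass
class SimOutput:
    """Generated data plus the ground truth it was generated from."""

    Y: BinaryTensor
    theta_true: np.ndarray | None
    prob_true: np.ndarray | None
    generator: dict
    seed: int


def matched_link(noise_family: str, sigma: float) -> LinkSpec:
    """The Bernoulli link exactly equivalent to the given threshold noise."""
    try:
        family = NOISE_TO_LINK[noise_family]
    except KeyError:
        raise ValueError(
            f"unknown noise family {noise_family!r}; choose from {sorted(NOISE_TO_LINK)}"
        ) from None
    return LinkSpec(family, sigma)


def matched_logistic_link(noise_family: str, sigma: float) -> LinkSpec:
    """A logistic link whose noise standard deviation matches the generator's.

    Fitting a logistic model to data quantized through Gaussian or Laplace
    noise is a deliberate (mild) family misspecification; matching the noise
    standard deviation keeps the fitted theta on the scale of the true one.
    For a Gaussian sd ``sigma`` the matched logistic scale is
    ``sigma * sqrt(3) / pi``.
    """
    if noise_family not in _NOISE_SD:
        raise ValueError(
            f"unknown noise family {noise_family!r}; choose from {sorted(_NOISE_SD)}"
        )
    sd = sigma * _NOISE_SD[noise_family]
    return LinkSpec("logistic", sd * math.sqrt(3.0) / math.pi)


def simulate_cp_threshold(
    dims,
    rank: int,
    sigma: float,
    noise_family: str = "gaussian",
    seed: int = 0,
) -> SimOutput:
    """Rank-R threshold model: ``Y = 1{Theta + E >= 0}``, ``|Theta|_max = 1``.

    Factor entries are i.i.d. Uniform[-1, 1]; the signal tensor is rescaled
    to unit max-norm; the noise is i.i.d. from ``noise_family`` at scale
    ``sigma`` (``sigma = 0`` gives the noiseless quantization).
    """
    if rank < 1:
        raise ValueError("rank must be at least 1")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if noise_family not in NOISE_TO_LINK:
        raise ValueError(
            f"unknown noise family {noise_family!r}; choose from {sorted(NOISE_TO_LINK)}"
        )
    dims = tuple(int(d) for d in dims)
    rng = np.random.default_rng(seed)
    mats = [rng.uniform(-1.0, 1.0, size=(d, rank)) for d in dims]
    theta = cp_reconstruct(CPFactors(mats))
    theta = theta / np.abs(theta).max()
    if sigma == 0.0:
        noise = np.zeros(dims)
    elif noise_family == "gaussian":
        noise = rng.normal(0.0, sigma, size=dims)
    elif noise_family == "logistic":
        noise = rng.logistic(0.0, sigma, size=dims)
    else:
        noise = rng.laplace(0.0, sigma, size=dims)
    Y = BinaryTensor((theta + noise >= 0.0).astype(np.int8))
    return SimOutput(
        Y=Y,
        theta_true=theta,
        prob_true=None,
        generator={
            "model": "cp_threshold",
            "dims": dims,
            "rank": rank,
            "sigma": sigma,
            "noise_family": noise_family,
        },
        seed=seed,
    )


def simulate_multiway_block(
    dims,
    n_blocks: int = 5,
    mean_model: str = "combinatorial",
    seed: int = 0,
) -> SimOutput:
    """Order-3 stochastic multi-way block model on the probit scale.

    Each mode's indices are dealt round-robin to ``n_blocks`` groups after a
    seeded shuffle (all blocks non-empty).  The block means are Uniform[-1,1]
    draws: per-cell (combinatorial), a sum of three per-mode effects
    (additive), or their product (multiplicative).  The probability tensor is
    the probit transform of the block-constant latent tensor.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3:
        raise ValueError("the block model generator is order-3")
    if n_blocks > min(dims):
        raise ValueError("n_blocks cannot exceed the smallest dimension")
    if mean_model not in ("combinatorial", "additive", "multiplicative"):
        raise ValueError(f"unknown mean model {mean_model!r}")
    rng = np.random.default_rng(seed)
    memberships = []
    for d in dims:
        perm = rng.permutation(d)
        labels = np.empty(d, dtype=int)
        labels[perm] = np.arange(d) % n_blocks
        memberships.append(labels)
    B = n_blocks
    mus = None
    if mean_model == "combinatorial":
        core = rng.uniform(-1.0, 1.0, size=(B, B, B))
    else:
        mus = [rng.uniform(-1.0, 1.0, size=B) for _ in range(3)]
        if mean_model == "additive":
            core = mus[0][:, None, None] + mus[1][None, :, None] + mus[2][None, None, :]
        else:
            core = mus[0][:, None, None] * mus[1][None, :, None] * mus[2][None, None, :]
    latent = core[np.ix_(memberships[0], memberships[1], memberships[2])]
    prob = ndtr(latent)
    Y = BinaryTensor((rng.random(dims) < prob).astype(np.int8))
    return SimOutput(
        Y=Y,
        theta_true=None,
        prob_true=prob,
        generator={
            "model": "multiway_block",
            "dims": dims,
            "n_blocks": n_blocks,
            "mean_model": mean_model,
            "memberships": [m.tolist() for m in memberships],
            "core": core.tolist(),
            "mode_means": None if mus is None else [m.tolist() for m in mus],
        },
        seed=seed,
    )


def simulate_boolean(
    dims,
    rank: int,
    flip_prob: float = 0.1,
    beta_params: tuple[float, float] = (2.0, 4.0),
    seed: int = 0,
) -> SimOutput:
    """Boolean OR-AND tensor with Beta factor probabilities and flip noise.

    Factor cell probabilities are i.i.d. Beta(a, b); factor bits are
    Bernoulli draws; the noiseless entry is the OR over components of the AND
    of its three factor bits; entries are then flipped independently with
    ``flip_prob``.  ``prob_true`` records the pre-flip conditional mean
    ``1 - prod_r (1 - p^a p^b p^c)``.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3:
        raise ValueError("the boolean generator is order-3")
    if rank < 1:
        raise ValueError("rank must be at least 1")
    if not 0.0 <= flip_prob < 1.0:
        raise ValueError("flip_prob must lie in [0, 1)")
    a, b = beta_params
    rng = np.random.default_rng(seed)
    probs = [rng.beta(a, b, size=(d, rank)) for d in dims]
    bits = [(rng.random((d, rank)) < p) for d, p in zip(dims, probs)]
    none_active = np.ones(dims)
    clean = np.zeros(dims, dtype=bool)
    for r in range(rank):
        and_r = (
            bits[0][:, r][:, None, None]
            & bits[1][:, r][None, :, None]
            & bits[2][:, r][None, None, :]
        )
        clean |= and_r
        none_active *= 1.0 - (
            probs[0][:, r][:, None, None]
            * probs[1][:, r][None, :, None]
            * probs[2][:, r][None, None, :]
        )
    prob_true = 1.0 - none_active
    flips = rng.random(dims) < flip_prob
    Y = BinaryTensor((clean ^ flips).astype(np.int8))
    return SimOutput(
        Y=Y,
        theta_true=None,
        prob_true=prob_true,
        generator={
            "model": "boolean",
            "dims": dims,
            "rank": rank,
            "flip_prob": flip_prob,
            "beta_params": (a, b),
        },
        seed=seed,
    )


def boolean_mean_probability(rank: int,
                             beta_params: tuple[float, float] = (2.0, 4.0)) -> float:
    """Expected pre-flip entry probability of the boolean model, closed form.

    Averaging ``1 - prod_r (1 - p^a p^b p^c)`` over the independent Beta
    factor probabilities gives ``1 - (1 - m^3)^R`` with ``m = a / (a + b)``.
    """
    if rank < 0:
        raise ValueError("rank must be nonnegative")
    a, b = beta_params
    m = a / (a + b)
    return float(1.0 - (1.0 - m**3) ** rank)
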