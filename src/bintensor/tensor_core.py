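"""CP/tensor algebra, factor normalization, and coordinate-format I/O.

The conventions used throughout the package are fixed here:

* internal indices are 0-based; the ``.tns`` coordinate files are 1-based;
* the mode-``k`` unfolding places mode ``k`` on the rows and ravels the
  remaining modes in ascending order, first-listed slowest (C order), which
  is exactly the row order of the Khatri-Rao product of the remaining factor
  matrices taken in ascending mode order.  The identity

      unfold(cp_reconstruct(A), k) == A_k @ khatri_rao(A_{-k}).T

  therefore holds entrywise and is enforced by the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import reduce
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import khatri_rao as _khatri_rao_pair

__all__ = [
    "BinaryTensor",
    "CPFactors",
    "cp_reconstruct",
    "khatri_rao",
    "unfold",
    "refold",
    "normalize_factors",
    "effective_num_params",
    "read_coordinate_tensor",
    "write_coordinate_tensor",
    "export_factors",
    "load_factors",
]


@dataclass
class BinaryTensor:
    """An order-K array with entries in {0, 1} and an optional observation mask.

    ``mask`` is boolean with the same shape; ``True`` marks an observed entry.
    ``mask is None`` means fully observed.  No mode-k slice may be entirely
    missing: the alternating algorithm fits one GLM per slice and a fully
    missing slice leaves that row of the factor matrix unidentified.
    """

    data: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim < 2:
            raise ValueError("tensor order must be at least 2")
        if self.data.size == 0:
            raise ValueError("all dimensions must be positive")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("tensor entries must be exactly 0 or 1")
        self.data = self.data.astype(np.int8, copy=False)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match "
                    f"tensor shape {self.data.shape}"
                )
            _check_no_missing_slice(self.mask)

    @property
    def dims(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def order(self) -> int:
        return self.data.ndim

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum()) if self.mask is not None else self.data.size


def _check_no_missing_slice(mask: np.ndarray) -> None:
    for k in range(mask.ndim):
        observed_per_slice = unfold(mask, k).any(axis=1)
        if not observed_per_slice.all():
            j = int(np.flatnonzero(~observed_per_slice)[0])
            raise ValueError(
                f"completely missing subtensor: slice {j} of mode {k} "
                "has no observed entries"
            )


@dataclass
class CPFactors:
    """K factor matrices of a rank-R CP representation.

    After :func:`normalize_factors`, the columns of modes ``0..K-2`` have unit
    Euclidean norm and the component scales (including signs pushed out of the
    leading modes) live in the mode ``K-1`` columns.
    """

    factors: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.factors) < 2:
            raise ValueError("CP factors require at least 2 modes")
        self.factors = [np.asarray(f, dtype=float) for f in self.factors]
        ranks = {f.shape[1] for f in self.factors}
        if len(ranks) != 1:
            raise ValueError(f"factor matrices have mismatched column counts: {ranks}")

    @property
    def rank(self) -> int:
        return self.factors[0].shape[1]

    @property
    def order(self) -> int:
        return len(self.factors)

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(f.shape[0] for f in self.factors)

    def copy(self) -> "CPFactors":
        return CPFactors([f.copy() for f in self.factors])


def khatri_rao(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Column-wise Kronecker product, first-listed matrix slowest.

    Column ``r`` of the result is ``kron(m1[:, r], m2[:, r], ...)`` in list
    order, so rows ravel the per-matrix row indices in C order.
    """
    matrices = [np.asarray(m, dtype=float) for m in matrices]
    if not matrices:
        raise ValueError("khatri_rao requires at least one matrix")
    ranks = {m.shape[1] for m in matrices}
    if len(ranks) != 1:
        raise ValueError(f"matrices have mismatched column counts: {ranks}")
    if len(matrices) == 1:
        return matrices[0].copy()
    return reduce(_khatri_rao_pair, matrices)


def cp_reconstruct(factors: CPFactors) -> np.ndarray:
    """Evaluate the CP sum of outer products as a dense tensor."""
    dims = factors.dims
    if factors.rank == 0:
        return np.zeros(dims)
    rest = khatri_rao(factors.factors[1:])
    return (factors.factors[0] @ rest.T).reshape(dims)


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding: rows index the given mode (0-based)."""
    tensor = np.asarray(tensor)
    if not 0 <= mode < tensor.ndim:
        raise ValueError(f"mode {mode} out of range for order-{tensor.ndim} tensor")
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def refold(matrix: np.ndarray, mode: int, dims: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of shape ``dims``."""
    dims = tuple(dims)
    if not 0 <= mode < len(dims):
        raise ValueError(f"mode {mode} out of range for order-{len(dims)} tensor")
    shape = (dims[mode],) + dims[:mode] + dims[mode + 1 :]
    return np.moveaxis(np.asarray(matrix).reshape(shape), 0, mode)


def normalize_factors(factors: CPFactors) -> CPFactors:
    """Push column norms and signs of modes 0..K-2 into the last mode.

    Sign convention: in each leading mode, the entry of largest magnitude in
    every column is made nonnegative (compensating sign absorbed by the last
    mode), which makes the operation idempotent.  Reconstruction is invariant.
    A column of exact zeros in a leading mode zeroes that component's scale.
    """
    mats = [f.copy() for f in factors.factors]
    R = factors.rank
    if R == 0:
        return CPFactors(mats)
    scale = np.ones(R)
    for k in range(len(mats) - 1):
        norms = np.linalg.norm(mats[k], axis=0)
        zero = norms == 0.0
        if zero.any():
            warnings.warn(
                f"mode {k} has {int(zero.sum())} all-zero column(s); "
                "component scale set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            scale[zero] = 0.0
            mats[k][0, zero] = 1.0  # replace by e_1 to keep unit columns
            norms[zero] = 1.0
        # columns already unit to machine precision are left untouched so the
        # operation is exactly idempotent
        renorm = np.abs(norms - 1.0) > 8 * np.finfo(float).eps
        mats[k][:, renorm] /= norms[renorm]
        scale[renorm] *= norms[renorm]
        top = np.abs(mats[k]).argmax(axis=0)
        signs = np.sign(mats[k][top, np.arange(R)])
        signs[signs == 0.0] = 1.0
        mats[k] *= signs
        scale *= signs
    mats[-1] = mats[-1] * scale
    return CPFactors(mats)


def effective_num_params(dims: Sequence[int], rank: int) -> int:
    """Effective parameter count of a rank-R CP model.

    ``R(d1 + d2) - R^2`` for matrices (nonsingular-transformation
    indeterminacy) and ``R(sum_k d_k - K + 1)`` for order K >= 3 (scaling
    indeterminacy only).
    """
    if rank < 0:
        raise ValueError("rank must be nonnegative")
    dims = tuple(int(d) for d in dims)
    K = len(dims)
    if K < 2:
        raise ValueError("tensor order must be at least 2")
    if K == 2:
        return rank * sum(dims) - rank**2
    return rank * (sum(dims) - K + 1)


# ---------------------------------------------------------------------------
# Coordinate (.tns) I/O: whitespace-separated, 1-based indices, last column
# the binary value.  A companion mask file lists the observed coordinates.
# ---------------------------------------------------------------------------


def _parse_coords(line: str, lineno: int, dims: tuple[int, ...], n_fields: int,
                  path: str) -> tuple[tuple[int, ...], list[str]]:
    parts = line.split()
    if len(parts) != n_fields:
        raise ValueError(
            f"{path}:{lineno}: expected {n_fields} whitespace-separated "
            f"fields, got {len(parts)}"
        )
    try:
        idx = tuple(int(p) for p in parts[: len(dims)])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer index") from exc
    for k, (i, d) in enumerate(zip(idx, dims)):
        if not 1 <= i <= d:
            raise ValueError(
                f"{path}:{lineno}: index {i} out of bounds for mode {k} "
                f"(size {d}, 1-based)"
            )
    return tuple(i - 1 for i in idx), parts


def read_coordinate_tensor(
    path: str | Path,
    dims: Sequence[int],
    mask_path: str | Path | None = None,
) -> BinaryTensor:
    """Read a FROSTT-style coordinate file into a dense :class:`BinaryTensor`.

    Without a mask file, coordinates absent from the file are 0 (dense
    semantics).  With a mask file of observed coordinates, unlisted observed
    entries are 0 and coordinates absent from the mask are missing.
    """
    dims = tuple(int(d) for d in dims)
    data = np.zeros(dims, dtype=np.int8)
    seen: set[tuple[int, ...]] = set()
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx, parts = _parse_coords(line, lineno, dims, len(dims) + 1, str(path))
            if parts[-1] not in ("0", "1"):
                raise ValueError(
                    f"{path}:{lineno}: non-binary value {parts[-1]!r}"
                )
            if idx in seen:
                raise ValueError(f"{path}:{lineno}: duplicated coordinate")
            seen.add(idx)
            data[idx] = int(parts[-1])

    mask = None
    if mask_path is not None:
        mask_path = Path(mask_path)
        mask = np.zeros(dims, dtype=bool)
        seen_mask: set[tuple[int, ...]] = set()
        with open(mask_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                idx, _ = _parse_coords(line, lineno, dims, len(dims), str(mask_path))
                if idx in seen_mask:
                    raise ValueError(f"{mask_path}:{lineno}: duplicated coordinate")
                seen_mask.add(idx)
                mask[idx] = True
        listed_unobserved = seen - seen_mask
        if listed_unobserved:
            idx = sorted(listed_unobserved)[0]
            raise ValueError(
                f"{path}: coordinate {tuple(i + 1 for i in idx)} has a value "
                "but is absent from the mask file"
            )
        data[~mask] = 0
    return BinaryTensor(data, mask)


def write_coordinate_tensor(
    tensor: BinaryTensor,
    path: str | Path,
    mask_path: str | Path | None = None,
) -> None:
    """Write the 1-entries of ``tensor`` as 1-based coordinate lines.

    If the tensor carries a mask, the observed coordinates are written to
    ``mask_path`` (default: ``path`` with a ``.mask.tns`` suffix) so that a
    read round trip reproduces both data and mask exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for idx in np.argwhere(tensor.data == 1):
            fh.write(" ".join(str(i + 1) for i in idx) + " 1\n")
    if tensor.mask is not None:
        if mask_path is None:
            mask_path = path.with_suffix(".mask.tns")
        with open(mask_path, "w") as fh:
            for idx in np.argwhere(tensor.mask):
                fh.write(" ".join(str(i + 1) for i in idx) + "\n")


def export_factors(factors: CPFactors, prefix: str | Path) -> list[Path]:
    """Write per-mode factor matrices as TSV plus a scales vector.

    All modes are written with unit-norm columns; the component scales
    ``lambda_r >= 0`` go to ``<prefix>_scales.tsv``.  Signs stay in the last
    mode's columns.
    """
    prefix = Path(prefix)
    normalized = normalize_factors(factors)
    mats = [f.copy() for f in normalized.factors]
    lam = np.linalg.norm(mats[-1], axis=0)
    safe = np.where(lam == 0.0, 1.0, lam)
    mats[-1] /= safe
    paths = []
    for k, mat in enumerate(mats):
        p = prefix.parent / f"{prefix.name}_mode{k + 1}.tsv"
        np.savetxt(p, mat, delimiter="\t")
        paths.append(p)
    p = prefix.parent / f"{prefix.name}_scales.tsv"
    np.savetxt(p, lam, delimiter="\t")
    paths.append(p)
    return paths


def load_factors(prefix: str | Path, order: int) -> CPFactors:
    """Read factors written by :func:`export_factors`."""
    prefix = Path(prefix)
    mats = []
    for k in range(order):
        mat = np.loadtxt(prefix.parent / f"{prefix.name}_mode{k + 1}.tsv",
                         delimiter="\t", ndmin=2)
        mats.append(mat)
    lam = np.loadtxt(prefix.parent / f"{prefix.name}_scales.tsv",
                     delimiter="\t", ndmin=1)
    mats[-1] = mats[-1] * lam
    return CPFactors(mats)
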