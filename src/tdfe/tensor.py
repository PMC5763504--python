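"""Dense tensors and full higher-order singular value decomposition (HOSVD).

The decomposition used throughout is the plain (untruncated) HOSVD: the
factor matrix of every mode is the matrix of left singular vectors of that
mode's unfolding, and the core tensor is the data contracted with all factor
transposes,

    x[i1, ..., im] = sum_{l1..lm} G(l1, ..., lm) * U1[i1, l1] * ... * Um[im, lm].

Because every factor is orthonormal the decomposition is exact, preserves the
Frobenius norm (``|G|_F = |X|_F``) and the core is all-orthogonal (slices
along any mode are mutually orthogonal).

Conventions frozen here for reproducibility:

* **Unfolding** -- mode-``k`` unfolding has the mode-``k`` index as rows and
  the remaining modes as columns in lexicographic order (original mode order,
  earlier modes varying slowest).  This is what
  ``np.moveaxis(x, k, 0).reshape(shape[k], -1)`` produces in C order.
* **Rank** -- each factor keeps ``min(dim_k, prod of other dims)`` columns;
  beyond that the singular values are exactly zero, so nothing is lost.  For
  a gene mode with tens of thousands of rows this avoids a square factor.
* **Sign** -- each factor column is flipped so that its largest-magnitude
  entry is positive (ties broken by lowest position); the core absorbs the
  flips, so the reconstruction is unchanged.
* **ℓ indices** -- user-facing singular-vector indices are 1-based,
  matching the standard ℓ notation of the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DenseTensor",
    "HOSVDResult",
    "CoreEntry",
    "unfold",
    "fold",
    "hosvd",
    "reconstruct",
    "rank_core",
    "find_contrast_vector",
]


@dataclass(frozen=True)
class DenseTensor:
    """An m-mode array of reals with named modes and per-mode category labels.

    Values are dimensionless (standardized expression); cells that were
    zero-filled for missing observations are exact zeros.
    """

    values: np.ndarray
    mode_names: tuple[str, ...]
    mode_categories: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mode_names", tuple(self.mode_names))
        object.__setattr__(
            self, "mode_categories", tuple(tuple(c) for c in self.mode_categories)
        )
        if len(self.mode_names) != values.ndim:
            raise ValueError(
                f"{len(self.mode_names)} mode names for a {values.ndim}-mode tensor"
            )
        if len(self.mode_categories) != values.ndim:
            raise ValueError(
                f"{len(self.mode_categories)} category lists for a "
                f"{values.ndim}-mode tensor"
            )
        for name, cats, dim in zip(self.mode_names, self.mode_categories, values.shape):
            if len(cats) != dim:
                raise ValueError(
                    f"mode {name!r}: {len(cats)} categories for dimension {dim}"
                )
        if not np.all(np.isfinite(values)):
            raise ValueError("tensor values must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def mode_index(self, mode: int | str) -> int:
        """Resolve a mode given as a 0-based position or a mode name."""
        if isinstance(mode, str):
            try:
                return self.mode_names.index(mode)
            except ValueError:
                raise ValueError(
                    f"unknown mode {mode!r}; modes are {self.mode_names}"
                ) from None
        mode = int(mode)
        if not 0 <= mode < self.ndim:
            raise ValueError(f"mode index {mode} out of range for {self.ndim} modes")
        return mode


@dataclass(frozen=True)
class HOSVDResult:
    """Core tensor plus one orthonormal factor matrix per mode.

    ``factors[k]`` has the mode-``k`` singular value vectors as columns
    (column ℓ-1 is the ℓ-th singular value vector).
    """

    core: np.ndarray
    factors: tuple[np.ndarray, ...]
    mode_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "core", np.asarray(self.core, dtype=float))
        object.__setattr__(
            self, "factors", tuple(np.asarray(f, dtype=float) for f in self.factors)
        )
        object.__setattr__(self, "mode_names", tuple(self.mode_names))
        if self.core.ndim != len(self.factors):
            raise ValueError("one factor matrix per core mode is required")
        for k, (f, r) in enumerate(zip(self.factors, self.core.shape)):
            if f.ndim != 2 or f.shape[1] != r:
                raise ValueError(
                    f"factor {k} has shape {f.shape}, expected (*, {r})"
                )

    @property
    def ndim(self) -> int:
        return self.core.ndim

    def mode_index(self, mode: int | str) -> int:
        if isinstance(mode, str):
            try:
                return self.mode_names.index(mode)
            except ValueError:
                raise ValueError(
                    f"unknown mode {mode!r}; modes are {self.mode_names}"
                ) from None
        mode = int(mode)
        if not 0 <= mode < self.ndim:
            raise ValueError(f"mode index {mode} out of range for {self.ndim} modes")
        return mode


@dataclass(frozen=True, order=True)
class CoreEntry:
    """A single signed core-tensor value at a 1-based ℓ index tuple."""

    index_tuple: tuple[int, ...]
    value: float


def unfold(tensor: DenseTensor | np.ndarray, mode: int | str) -> np.ndarray:
    """Mode-``mode`` unfolding (matricization) of a tensor.

    Rows are indexed by the chosen mode; columns run over the remaining modes
    in their original order, earlier modes varying slowest.
    """
    if isinstance(tensor, DenseTensor):
        k = tensor.mode_index(mode)
        values = tensor.values
    else:
        values = np.asarray(tensor)
        k = int(mode)
        if not 0 <= k < values.ndim:
            raise ValueError(f"mode index {k} out of range for {values.ndim} modes")
    return np.moveaxis(values, k, 0).reshape(values.shape[k], -1)


def fold(matrix: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`unfold` for the same column convention."""
    shape = tuple(int(s) for s in shape)
    if not 0 <= mode < len(shape):
        raise ValueError(f"mode index {mode} out of range for {len(shape)} modes")
    rest = shape[:mode] + shape[mode + 1 :]
    arr = np.asarray(matrix).reshape((shape[mode],) + rest)
    return np.moveaxis(arr, 0, mode)


def _mode_dot(values: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` product: contract axis ``mode`` with ``matrix``'s columns.

    Returns a tensor whose mode-``mode`` dimension is ``matrix.shape[0]``.
    """
    out = np.tensordot(matrix, np.moveaxis(values, mode, 0), axes=([1], [0]))
    return np.moveaxis(out, 0, mode)


def hosvd(tensor: DenseTensor | np.ndarray) -> HOSVDResult:
    """Full higher-order SVD of a dense tensor.

    The factor of mode ``k`` holds the left singular vectors of the mode-``k``
    unfolding, truncated to ``min(dim_k, prod of other dims)`` columns (the
    remaining directions carry exactly zero singular value).  The core is the
    tensor contracted with every factor transpose.
    """
    if isinstance(tensor, DenseTensor):
        values = tensor.values
        mode_names = tensor.mode_names
    else:
        values = np.asarray(tensor, dtype=float)
        mode_names = tuple(f"mode{k}" for k in range(values.ndim))
    if not np.all(np.isfinite(values)):
        raise ValueError("tensor values must be finite")
    if values.ndim < 1 or min(values.shape) < 1:
        raise ValueError("every tensor dimension must be >= 1")

    factors: list[np.ndarray] = []
    for k in range(values.ndim):
        m = unfold(values, k)
        # economy SVD keeps min(rows, cols) columns: exactly the nonzero rank bound
        u, _, _ = np.linalg.svd(m, full_matrices=False)
        factors.append(_fix_signs(u))

    core = values
    for k, u in enumerate(factors):
        core = _mode_dot(core, u.T, k)
    return HOSVDResult(core=core, factors=tuple(factors), mode_names=mode_names)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|entry| component is positive."""
    u = u.copy()
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


def reconstruct(result: HOSVDResult) -> np.ndarray:
    """Recompose the tensor: core multiplied by every factor along its mode.

    Exact (up to round-off) for a full HOSVD because no nonzero direction was
    truncated.
    """
    values = result.core
    for k, u in enumerate(result.factors):
        values = _mode_dot(values, u, k)
    return values


def rank_core(
    result: HOSVDResult,
    fixed: Mapping[int | str, int] | None = None,
) -> list[CoreEntry]:
    """Core entries matching ``fixed`` mode indices, largest |G| first.

    ``fixed`` maps a mode (0-based position or name) to a **1-based** ℓ index;
    entries whose index tuple disagrees with any fixed value are dropped.
    Ties in |G| are broken by lexicographic index tuple (lowest first).
    """
    fixed = fixed or {}
    fixed_pos: dict[int, int] = {}
    for mode, l in fixed.items():
        k = result.mode_index(mode)
        if not 1 <= int(l) <= result.core.shape[k]:
            raise ValueError(
                f"fixed index {l} out of range 1..{result.core.shape[k]} for mode {k}"
            )
        fixed_pos[k] = int(l)

    entries: list[CoreEntry] = []
    it = np.nditer(result.core, flags=["multi_index"])
    for value in it:
        idx = it.multi_index
        if any(idx[k] + 1 != l for k, l in fixed_pos.items()):
            continue
        entries.append(
            CoreEntry(index_tuple=tuple(i + 1 for i in idx), value=float(value))
        )
    entries.sort(key=lambda e: (-abs(e.value), e.index_tuple))
    return entries


def find_contrast_vector(
    result: HOSVDResult,
    mode: int | str,
    contrast: Sequence[float],
) -> int:
    """1-based index of the factor column best aligned with a contrast.

    Returns ``argmax_l |contrast . column_l| / ||column_l||`` over the columns
    of the chosen mode's factor (columns are unit norm, so this is the
    absolute projection).  Automates reading a condition pattern -- e.g. the
    control-vs-treated difference with contrast ``(+1, -1)``, or a tissue
    coexpression group with a ±1 membership vector -- off the factor matrix.
    Ties go to the lowest index.
    """
    k = result.mode_index(mode)
    u = result.factors[k]
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (u.shape[0],):
        raise ValueError(
            f"contrast length {contrast.size} does not match mode dimension {u.shape[0]}"
        )
    norms = np.linalg.norm(u, axis=0)
    norms[norms == 0] = np.inf
    scores = np.abs(contrast @ u) / norms
    return int(np.argmax(scores)) + 1
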