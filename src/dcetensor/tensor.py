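"""Third-order tensor algebra: unfolding, mode products, HOSVD.

A 3D volume is treated as a third-order tensor X of shape (I1, I2, I3).
The mode-i unfolding used throughout is

    unfold(X, i)[a, :] = X with axis i moved first, remaining axes
    flattened in C (row-major) order,

so ``unfold`` has shape (I_i, prod of the other dims) and ``fold`` is its
exact inverse.  The higher-order SVD (Tucker/HOSVD) factorizes

    X = core x_1 A^1 x_2 A^2 x_3 A^3,

where A^i holds the leading left singular vectors of unfold(X, i) and the
all-orthogonal core is X multiplied by the transposed bases.  Each
singular vector is oriented so that its largest-magnitude entry is
positive, which makes the decomposition deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ParameterError

__all__ = ["HOSVDFactors", "unfold", "fold", "mode_multiply", "hosvd_decompose", "reconstruct"]


def _check_mode(X: np.ndarray, mode: int) -> None:
    if mode not in (0, 1, 2):
        raise ParameterError(f"mode must be 0, 1 or 2, got {mode}")
    if X.ndim != 3:
        raise DimensionError(f"expected a 3rd-order tensor, got ndim {X.ndim}")


def unfold(X: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding, shape (I_mode, product of remaining dims)."""
    X = np.asarray(X, dtype=float)
    _check_mode(X, mode)
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def fold(M: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given full shape."""
    if mode not in (0, 1, 2):
        raise ParameterError(f"mode must be 0, 1 or 2, got {mode}")
    rest = [s for i, s in enumerate(shape) if i != mode]
    M = np.asarray(M, dtype=float)
    if M.shape[1] != int(np.prod(rest)):
        raise DimensionError(
            f"matrix with {M.shape[1]} columns cannot fold into shape {shape} along mode {mode}"
        )
    return np.moveaxis(M.reshape(M.shape[0], *rest), 0, mode)


def mode_multiply(X: np.ndarray, M: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` product X x_mode M (M has I_mode columns)."""
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    _check_mode(X, mode)
    if M.ndim != 2 or M.shape[1] != X.shape[mode]:
        raise DimensionError(
            f"matrix shape {M.shape} incompatible with tensor shape {X.shape} at mode {mode}"
        )
    out_shape = tuple(M.shape[0] if i == mode else s for i, s in enumerate(X.shape))
    return fold(M @ unfold(X, mode), mode, out_shape)


def _orient_columns(U: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    if U.size == 0:
        return U
    idx = np.abs(U).argmax(axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


@dataclass
class HOSVDFactors:
    """HOSVD of one tensor: three orthonormal mode bases plus the core."""

    mode_bases: tuple[np.ndarray, np.ndarray, np.ndarray]
    core: np.ndarray
    frame_index: int | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b.shape[0] for b in self.mode_bases)  # type: ignore[return-value]


def hosvd_decompose(
    X: np.ndarray, ranks: tuple[int, int, int] | None = None, frame_index: int | None = None
) -> HOSVDFactors:
    """Higher-order SVD of a third-order tensor.

    Parameters
    ----------
    X : ndarray (I1, I2, I3)
    ranks : optional per-mode truncation ranks; defaults to full
        (R_i = min(I_i, prod of the other dims)), at which the
        factorization is exact.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise DimensionError(f"expected a 3rd-order tensor, got ndim {X.ndim}")
    bases: list[np.ndarray] = []
    for mode in range(3):
        Xm = unfold(X, mode)
        full_rank = min(Xm.shape)
        r = full_rank if ranks is None else int(ranks[mode])
        if r < 1 or r > X.shape[mode]:
            raise ParameterError(
                f"rank {r} invalid for mode {mode} of dimension {X.shape[mode]}"
            )
        U, _, _ = np.linalg.svd(Xm, full_matrices=False)
        bases.append(_orient_columns(U[:, : min(r, full_rank)]))
    core = X
    for mode in range(3):
        core = mode_multiply(core, bases[mode].T, mode)
    return HOSVDFactors(tuple(bases), core, frame_index=frame_index)


def reconstruct(factors: HOSVDFactors) -> np.ndarray:
    """core x_1 A^1 x_2 A^2 x_3 A^3 — exact at full ranks."""
    out = factors.core
    for mode, basis in enumerate(factors.mode_bases):
        out = mode_multiply(out, basis, mode)
    return out
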