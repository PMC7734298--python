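"""Order-3 tensor algebra: unfoldings, mode-n products, and the higher-order SVD.

Conventions used throughout the package
---------------------------------------
Modes are numbered 1, 2, 3 (matching the usual multilinear-algebra notation,
where mode 1 of an ROI time-series tensor is *time*, mode 2 is *region* and
mode 3 is *sample*).

``unfold(t, n)`` moves mode ``n`` to the front and reshapes in C (row-major)
order.  The columns of the result are the mode-``n`` fibers; the remaining
modes keep their original relative order, with the highest-numbered remaining
mode varying fastest.  Every routine in the package uses this single
convention, so folds and unfolds are mutually inverse and core/factor entries
are reproducible bit-for-bit across runs.

Sign indeterminacy of singular vectors is resolved deterministically: each
column of every factor matrix is flipped, if necessary, so that its
largest-magnitude entry is positive (ties broken by the lowest index); the
core tensor absorbs the flip.  Reconstruction errors and connectivity outputs
are invariant to this choice, but fixing it makes intermediate artifacts
comparable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TruncationRanks",
    "HOSVDResult",
    "TruncatedHOSVD",
    "unfold",
    "fold",
    "mode_n_product",
    "multi_mode_product",
    "frobenius_norm",
    "mode_singular_values",
    "hosvd",
    "truncate",
]

_VALID_MODES = (1, 2, 3)

#: Default tolerance for exact algebraic identities (orthogonality,
#: reconstruction of an untruncated decomposition).
EXACT_TOL = 1e-10
#: Default tolerance for iterative / estimated quantities.
ESTIMATE_TOL = 1e-6


def _as_tensor3(data) -> np.ndarray:
    a = np.asarray(data, dtype=float)
    if a.ndim != 3:
        raise ValueError(f"expected an order-3 tensor, got array of order {a.ndim}")
    if not np.all(np.isfinite(a)):
        raise ValueError("tensor contains non-finite entries (NaN or Inf)")
    return a


def _check_mode(mode: int) -> int:
    if mode not in _VALID_MODES:
        raise ValueError(f"invalid mode {mode!r}; allowed modes are 1, 2 and 3")
    return mode


@dataclass(frozen=True)
class TruncationRanks:
    """Multilinear truncation ranks ``(k1, k2, k3)`` for an order-3 tensor.

    ``k1`` acts on the time mode, ``k2`` on the region mode and ``k3`` on the
    sample mode of an ROI time-series tensor.
    """

    k1: int
    k2: int
    k3: int

    def __post_init__(self) -> None:
        for name, k in zip(("k1", "k2", "k3"), self):
            if int(k) != k or k < 1:
                raise ValueError(f"{name} must be a positive integer, got {k!r}")

    def __iter__(self):
        return iter((self.k1, self.k2, self.k3))

    def validate(self, shape: tuple[int, int, int]) -> None:
        for name, k, dim in zip(("k1", "k2", "k3"), self, shape):
            if k > dim:
                raise ValueError(
                    f"rank {name}={k} exceeds the corresponding tensor dimension {dim}"
                )


@dataclass
class HOSVDResult:
    """Full higher-order SVD of an order-3 tensor ``A``.

    ``A = (U1, U2, U3) . core`` with ``Uk`` the (square, orthogonal) left
    singular matrix of the mode-``k`` unfolding and ``core`` the all-orthogonal
    core tensor of the same shape as ``A``.  ``mode_singular_values[k-1]``
    holds the mode-``k`` singular values (slice norms of the core, equal to
    the singular values of the mode-``k`` unfolding, padded with zeros up to
    the mode dimension).
    """

    core: np.ndarray
    factors: list[np.ndarray]
    mode_singular_values: list[np.ndarray] = field(repr=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.core.shape

    def reconstruct(self) -> np.ndarray:
        return multi_mode_product(self.core, self.factors, (1, 2, 3))


@dataclass
class TruncatedHOSVD:
    """Rank-``(k1,k2,k3)`` truncation of an :class:`HOSVDResult`."""

    factors: list[np.ndarray]
    core: np.ndarray
    reconstruction: np.ndarray
    ranks: TruncationRanks


def unfold(t, mode: int) -> np.ndarray:
    """Matricize ``t`` along ``mode`` (1-based); columns are mode fibers."""
    a = _as_tensor3(t)
    _check_mode(mode)
    return np.moveaxis(a, mode - 1, 0).reshape(a.shape[mode - 1], -1)


def fold(m, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given ``shape``."""
    _check_mode(mode)
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError(f"shape must have three entries, got {shape}")
    moved = [shape[mode - 1]] + [s for i, s in enumerate(shape) if i != mode - 1]
    return np.moveaxis(np.asarray(m, dtype=float).reshape(moved), 0, mode - 1)


def mode_n_product(t, X, mode: int) -> np.ndarray:
    """Mode-``n`` product ``(X)_n . t``: multiply every mode-``n`` fiber by ``X``."""
    a = _as_tensor3(t)
    _check_mode(mode)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a matrix, got array of order {X.ndim}")
    if X.shape[1] != a.shape[mode - 1]:
        raise ValueError(
            f"dimension mismatch in mode-{mode} product: matrix has {X.shape[1]} "
            f"columns but the tensor's mode-{mode} dimension is {a.shape[mode - 1]}"
        )
    return np.moveaxis(np.tensordot(X, a, axes=(1, mode - 1)), 0, mode - 1)


def multi_mode_product(t, matrices, modes) -> np.ndarray:
    """Apply mode-``n`` products for several modes in sequence."""
    out = _as_tensor3(t)
    for X, mode in zip(matrices, modes):
        out = mode_n_product(out, X, mode)
    return out


def frobenius_norm(t) -> float:
    """Frobenius norm: square root of the sum of squared entries."""
    return float(np.linalg.norm(np.asarray(t, dtype=float)))


def mode_singular_values(t, mode: int) -> np.ndarray:
    """Mode-``k`` singular values: singular values of the mode-``k`` unfolding.

    Padded with zeros up to the mode-``k`` dimension, so the length always
    equals that dimension (the unfolding may be wide or tall).
    """
    a = _as_tensor3(t)
    s = np.linalg.svd(unfold(a, mode), compute_uv=False)
    out = np.zeros(a.shape[mode - 1])
    out[: s.size] = s
    return out


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(U), axis=0)  # argmax takes the lowest index on ties
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def hosvd(t) -> HOSVDResult:
    """Higher-order SVD of an order-3 tensor.

    The factor for each mode is the full left singular matrix of that mode's
    unfolding; the core is the input multiplied by the transposed factors in
    every mode.  The core inherits the all-orthogonality and ordering
    properties: distinct slices along any mode are mutually orthogonal, and
    slice norms along mode ``k`` are the (non-increasing) singular values of
    the mode-``k`` unfolding.
    """
    a = _as_tensor3(t)
    factors: list[np.ndarray] = []
    svals: list[np.ndarray] = []
    for mode in _VALID_MODES:
        U, s, _ = np.linalg.svd(unfold(a, mode), full_matrices=True)
        factors.append(_fix_signs(U))
        padded = np.zeros(a.shape[mode - 1])
        padded[: s.size] = s
        svals.append(padded)
    core = multi_mode_product(a, [U.T for U in factors], _VALID_MODES)
    return HOSVDResult(core=core, factors=factors, mode_singular_values=svals)


def truncate(h: HOSVDResult, ranks: TruncationRanks) -> TruncatedHOSVD:
    """Truncate a full HOSVD to multilinear rank ``(k1, k2, k3)``.

    Keeps the leading ``k_i`` singular vectors per mode and the matching core
    block.  The squared reconstruction error is bounded above by the sum of
    the discarded squared mode singular values over all three modes (the sum
    counts shared energy more than once, so the bound is in general not
    attained).
    """
    ranks.validate(h.shape)
    factors = [U[:, :k] for U, k in zip(h.factors, ranks)]
    core = h.core[: ranks.k1, : ranks.k2, : ranks.k3]
    reconstruction = multi_mode_product(core, factors, _VALID_MODES)
    return TruncatedHOSVD(
        factors=factors, core=core, reconstruction=reconstruction, ranks=ranks
    )


def truncation_error_bound(h: HOSVDResult, ranks: TruncationRanks) -> float:
    """Upper bound on the squared truncation error: discarded squared singular values."""
    ranks.validate(h.shape)
    return float(
        sum(np.sum(s[k:] ** 2) for s, k in zip(h.mode_singular_values, ranks))
    )
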