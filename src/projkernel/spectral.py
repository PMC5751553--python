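"""Symmetric eigendecomposition and the projection transform for indefinite kernels.

An indefinite kernel ``K`` (symmetric, at least one negative eigenvalue) is
rectified by the projection transform ``(I - lam * B B') K`` where the columns
of ``B`` span the negative eigenspace.  In the eigenbasis this multiplies each
negative eigenvalue by ``(1 - lam)`` and leaves the rest untouched, so

* ``lam = 1`` clips negative eigenvalues to zero (denoising),
* ``lam = 2`` negates them (flipping),
* any ``lam >= 1`` yields a positive semi-definite matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelMatrix",
    "SpectralDecomposition",
    "ProjectionResult",
    "decompose",
    "projection_factor",
    "project_kernel",
    "denoise_kernel",
    "flip_kernel",
    "is_psd",
]

_SYM_RTOL = 1e-10


def _as_square(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"kernel matrix must be square, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("kernel matrix contains non-finite entries")
    return arr


def _max_asymmetry(arr: np.ndarray) -> float:
    return float(np.max(np.abs(arr - arr.T))) if arr.size else 0.0


@dataclass(frozen=True)
class KernelMatrix:
    """A validated symmetric similarity matrix.

    Parameters
    ----------
    values:
        Square real matrix.  Must be symmetric to within a relative
        tolerance of 1e-10 unless ``symmetrize=True`` is passed, in which
        case the symmetric part ``(K + K') / 2`` is stored.
    """

    values: np.ndarray

    def __init__(self, values, *, symmetrize: bool = False):
        arr = _as_square(values)
        asym = _max_asymmetry(arr)
        scale = max(float(np.max(np.abs(arr))) if arr.size else 0.0, 1.0)
        if symmetrize:
            arr = (arr + arr.T) / 2.0
        elif asym > _SYM_RTOL * scale:
            raise ValueError(
                f"kernel matrix is not symmetric: max |K - K'| = {asym:.3e} "
                f"(relative tolerance {_SYM_RTOL:g})"
            )
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigensystem of a kernel with inertia bookkeeping.

    Eigenvalues are sorted ascending; ``eigenvectors`` columns are aligned
    with them and sign-fixed so the largest-magnitude entry of each column
    is positive.  ``neg_index`` (m) counts eigenvalues below
    ``-tol_rel * max(|d|, 1)``, ``pos_index`` (l) those above the threshold,
    ``zero_count`` the rest.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    neg_index: int
    zero_count: int
    pos_index: int
    tol: float

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def negative_basis(self) -> np.ndarray:
        """Columns spanning the negative eigenspace (the matrix B)."""
        return self.eigenvectors[:, : self.neg_index]


@dataclass(frozen=True)
class ProjectionResult:
    """Outcome of applying the projection transform at a given strength."""

    lam: float
    transformed: KernelMatrix
    psd_certified: bool
    min_eigenvalue: float


def decompose(K: KernelMatrix | np.ndarray, tol_rel: float = 1e-8) -> SpectralDecomposition:
    """Eigendecompose a symmetric kernel with deterministic conventions.

    Eigenvalues ascending (``numpy.linalg.eigh`` order); each eigenvector
    column is flipped, if needed, so its largest-magnitude entry is
    positive.  The inertia threshold is relative:
    ``d_i < -tol_rel * max(max|d|, 1)`` counts as negative.
    """
    if tol_rel <= 0:
        raise ValueError("tol_rel must be positive")
    if not isinstance(K, KernelMatrix):
        K = KernelMatrix(K)
    d, P = np.linalg.eigh(K.values)
    # sign convention: largest-magnitude entry of each column positive
    idx = np.argmax(np.abs(P), axis=0)
    signs = np.sign(P[idx, np.arange(P.shape[1])])
    signs[signs == 0] = 1.0
    P = P * signs
    scale = max(float(np.max(np.abs(d))) if d.size else 0.0, 1.0)
    thresh = tol_rel * scale
    m = int(np.count_nonzero(d < -thresh))
    l = int(np.count_nonzero(d > thresh))
    zero = d.size - m - l
    d = d.copy()
    d.flags.writeable = False
    P.flags.writeable = False
    return SpectralDecomposition(
        eigenvalues=d, eigenvectors=P, neg_index=m, zero_count=zero, pos_index=l, tol=thresh
    )


def projection_factor(decomp: SpectralDecomposition, lam: float) -> KernelMatrix:
    """The projection matrix ``I - lam * B B'``.

    Its spectrum is ``1 - lam`` with multiplicity m and ``1`` with
    multiplicity n - m; it shares eigenvectors with the source kernel.
    """
    n = decomp.n
    B = decomp.negative_basis
    if B.shape[1] == 0:
        return KernelMatrix(np.eye(n))
    F = np.eye(n) - lam * (B @ B.T)
    return KernelMatrix(F, symmetrize=True)


def _rebuild(decomp: SpectralDecomposition, new_eigenvalues: np.ndarray) -> np.ndarray:
    P = decomp.eigenvectors
    return (P * new_eigenvalues) @ P.T


def project_kernel(
    K: KernelMatrix | np.ndarray, lam: float, tol_rel: float = 1e-8
) -> ProjectionResult:
    """Apply the projection transform at strength ``lam``.

    The transformed kernel is rebuilt in the eigenbasis as
    ``P diag((1-lam) d_1, ..., (1-lam) d_m, d_{m+1}, ..., d_n) P'`` —
    algebraically equal to ``(I - lam B B') K`` but exactly symmetric in
    floating point.  A PSD certificate is issued when the smallest
    transformed eigenvalue is at least ``-1e-8 * max|d|``; this always
    holds for ``lam >= 1``.
    """
    if lam < 0:
        raise ValueError(f"projection strength lam must be >= 0, got {lam}")
    if not isinstance(K, KernelMatrix):
        K = KernelMatrix(K)
    decomp = decompose(K, tol_rel=tol_rel)
    m = decomp.neg_index
    d = decomp.eigenvalues
    scale = max(float(np.max(np.abs(d))) if d.size else 0.0, 1.0)
    if m == 0:
        new_d = d
        transformed = K  # identity on PSD input, bit-exact
    else:
        new_d = d.copy()
        new_d[:m] = (1.0 - lam) * new_d[:m]
        transformed = KernelMatrix(_rebuild(decomp, new_d), symmetrize=True)
    min_eig = float(np.min(new_d)) if d.size else 0.0
    certified = min_eig >= -1e-8 * scale
    return ProjectionResult(
        lam=float(lam), transformed=transformed, psd_certified=certified, min_eigenvalue=min_eig
    )


def denoise_kernel(K: KernelMatrix | np.ndarray, tol_rel: float = 1e-8) -> ProjectionResult:
    """Clip negative eigenvalues to zero (projection at ``lam = 1``)."""
    return project_kernel(K, 1.0, tol_rel=tol_rel)


def flip_kernel(K: KernelMatrix | np.ndarray, tol_rel: float = 1e-8) -> ProjectionResult:
    """Negate negative eigenvalues (projection at ``lam = 2``)."""
    return project_kernel(K, 2.0, tol_rel=tol_rel)


def is_psd(K: KernelMatrix | np.ndarray, tol_rel: float = 1e-8) -> tuple[bool, float]:
    """Whether the smallest eigenvalue exceeds ``-tol_rel * max(max|d|, 1)``.

    Returns the flag together with the smallest eigenvalue.
    """
    if not isinstance(K, KernelMatrix):
        K = KernelMatrix(K)
    d = np.linalg.eigvalsh(K.values)
    scale = max(float(np.max(np.abs(d))) if d.size else 0.0, 1.0)
    min_eig = float(d[0]) if d.size else 0.0
    return min_eig >= -tol_rel * scale, min_eig
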