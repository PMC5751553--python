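"""Bregman matrix divergences between kernel matrices.

For a strictly convex spectral generator phi, the Bregman matrix divergence is

    D_phi(K, K0) = phi(K) - phi(K0) - tr(grad phi(K0)' (K - K0)).

Four classical generators are provided (Mahalanobis, Frobenius, von-Neumann,
LogDet) plus the perturbed von-Neumann objective V(lam), a trace-factored
variant whose value along the projection family is a quadratic in the
projection strength lam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import KernelMatrix, SpectralDecomposition

__all__ = [
    "DivergenceValue",
    "PerturbedVNObjective",
    "mahalanobis_div",
    "frobenius_div",
    "von_neumann_div",
    "logdet_div",
    "perturbed_vn_objective",
    "pinv_traces",
]


@dataclass(frozen=True)
class DivergenceValue:
    name: str
    value: float

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class PerturbedVNObjective:
    """V(lam) = v2*lam^2 + v1*lam + v0, the perturbed von-Neumann objective.

    Along the projection family the trace-factored divergence
    ``tr(K~) tr(log K~ - log K0) + tr(-K~ + K0)`` evaluates, with
    pseudo-inverse traces t_i = tr(K0^+ p_i p_i'), to

        V(lam) = (sum_{i<=m}(1-lam) d_i + sum_{i>m} d_i)
                 * (sum_{i<=m}(1-lam) d_i t_i + sum_{i>m} d_i t_i)
                 + sum_{i<=m} d_i

    which is quadratic in lam; the coefficients are stored exactly so the
    vertex is available in closed form.  ``constant`` flags the degenerate
    m = 0 case where V does not depend on lam.
    """

    v2: float
    v1: float
    v0: float
    constant: bool
    decomposition: SpectralDecomposition

    def __call__(self, lam) -> np.ndarray | float:
        lam = np.asarray(lam, dtype=float)
        out = self.v2 * lam**2 + self.v1 * lam + self.v0
        return float(out) if out.ndim == 0 else out


def _pair(K, K0) -> tuple[np.ndarray, np.ndarray]:
    A = K.values if isinstance(K, KernelMatrix) else KernelMatrix(K).values
    B = K0.values if isinstance(K0, KernelMatrix) else KernelMatrix(K0).values
    if A.shape != B.shape:
        raise ValueError(f"kernel shapes differ: {A.shape} vs {B.shape}")
    return A, B


def mahalanobis_div(K, K0) -> DivergenceValue:
    """tr(K^2 - 2 K K0 + K0^2), i.e. tr((K - K0)^2) for symmetric arguments."""
    A, B = _pair(K, K0)
    diff = A - B
    return DivergenceValue("mahalanobis", float(np.trace(diff @ diff)))


def frobenius_div(K, K0) -> DivergenceValue:
    """Squared Frobenius norm of K - K0."""
    A, B = _pair(K, K0)
    return DivergenceValue("frobenius", float(np.sum((A - B) ** 2)))


def von_neumann_div(K, K0, tol_rel: float = 1e-8) -> DivergenceValue:
    """tr(K log K - K log K0 - K + K0) for PSD arguments.

    Matrix logarithms are taken in the eigenbasis with the 0 log 0 = 0
    convention.  The range of K must lie in the range of K0, otherwise the
    cross term diverges.
    """
    A, B = _pair(K, K0)
    da, Pa = np.linalg.eigh(A)
    db, Pb = np.linalg.eigh(B)
    scale_a = max(float(np.max(np.abs(da))) if da.size else 0.0, 1.0)
    scale_b = max(float(np.max(np.abs(db))) if db.size else 0.0, 1.0)
    tol_a, tol_b = tol_rel * scale_a, tol_rel * scale_b
    if np.any(da < -tol_a) or np.any(db < -tol_b):
        raise ValueError("von-Neumann divergence requires PSD arguments")
    da = np.clip(da, 0.0, None)
    db = np.clip(db, 0.0, None)

    # range containment: K must vanish on K0's null space
    null_b = Pb[:, db <= tol_b]
    if null_b.shape[1]:
        leak = float(np.max(np.abs(A @ null_b)))
        if leak > tol_a:
            raise ValueError(
                "range of K is not contained in range of K0 "
                f"(leakage {leak:.3e}); tr(K log K0) diverges"
            )

    def xlogx(x):
        out = np.zeros_like(x)
        nz = x > 0
        out[nz] = x[nz] * np.log(x[nz])
        return out

    tr_klogk = float(np.sum(xlogx(da)))
    # tr(K log K0) with log restricted to K0's range (K vanishes off it)
    pos_b = db > tol_b
    logB = (Pb[:, pos_b] * np.log(db[pos_b])) @ Pb[:, pos_b].T
    tr_klogk0 = float(np.trace(A @ logB))
    value = tr_klogk - tr_klogk0 - float(np.sum(da)) + float(np.sum(db))
    return DivergenceValue("von_neumann", value)


def logdet_div(K, K0, tol_rel: float = 1e-8) -> DivergenceValue:
    """tr(K K0^{-1}) - log det(K K0^{-1}) - n for strictly PD arguments.

    For indefinite kernels this numeric form is undefined; selection of the
    projection strength for those goes through the closed-form rule
    ``lambda_selection.lambda_opt_logdet`` instead.
    """
    A, B = _pair(K, K0)
    n = A.shape[0]
    da = np.linalg.eigvalsh(A)
    db = np.linalg.eigvalsh(B)
    tol_a = tol_rel * max(float(np.max(np.abs(da))) if da.size else 0.0, 1.0)
    tol_b = tol_rel * max(float(np.max(np.abs(db))) if db.size else 0.0, 1.0)
    if np.any(da <= tol_a) or np.any(db <= tol_b):
        raise ValueError(
            "LogDet divergence requires strictly positive definite arguments; "
            "for indefinite kernels use lambda_selection.lambda_opt_logdet"
        )
    M = np.linalg.solve(B, A)  # K0^{-1} K, same trace/det as K K0^{-1}
    sign, logabsdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise ValueError("log det(K K0^{-1}) undefined (non-positive determinant)")
    return DivergenceValue("logdet", float(np.trace(M)) - float(logabsdet) - n)


def pinv_traces(decomp: SpectralDecomposition, pinv_tol: float = 1e-8) -> np.ndarray:
    """t_i = tr(K0^+ p_i p_i') for the decomposition's own eigenpairs.

    Because p_i are eigenvectors of K0, the pseudo-inverse trace reduces to
    1/d_i when |d_i| exceeds ``pinv_tol * max|d|`` and 0 otherwise.
    """
    d = decomp.eigenvalues
    scale = max(float(np.max(np.abs(d))) if d.size else 0.0, 1.0)
    thresh = pinv_tol * scale
    t = np.zeros_like(d)
    keep = np.abs(d) > thresh
    t[keep] = 1.0 / d[keep]
    return t


def perturbed_vn_objective(
    decomp: SpectralDecomposition, pinv_tol: float = 1e-8
) -> PerturbedVNObjective:
    """Quadratic coefficients of the perturbed von-Neumann objective V(lam).

    With A = sum_{i<=m} d_i, T = sum_i d_i, G = sum_{i<=m} d_i t_i and
    R = sum_i d_i t_i the product form expands to

        V(lam) = (T - lam A)(R - lam G) + A
               = (A G) lam^2 - (A R + T G) lam + (T R + A).
    """
    d = decomp.eigenvalues
    m = decomp.neg_index
    t = pinv_traces(decomp, pinv_tol=pinv_tol)
    A = float(np.sum(d[:m]))
    T = float(np.sum(d))
    G = float(np.sum(d[:m] * t[:m]))
    R = float(np.sum(d * t))
    return PerturbedVNObjective(
        v2=A * G,
        v1=-(A * R + T * G),
        v0=T * R + A,
        constant=(m == 0),
        decomposition=decomp,
    )
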