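"""Deterministic synthetic fixtures: controlled-spectrum kernels and labeled problems.

Every generator is a pure function of its seed so tests and command-line
runs replay bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import LabeledProblem
from .kernels import FeatureMatrix
from .spectral import KernelMatrix

__all__ = [
    "SpectrumSpec",
    "make_spectrum_kernel",
    "random_orthonormal",
    "make_labeled_problem",
    "make_indefinite_problem",
]


@dataclass(frozen=True)
class SpectrumSpec:
    """Recipe for a kernel with a prescribed spectrum.

    Either pass explicit ``eigenvalues``, or a size/inertia recipe
    ``(n, m)`` with magnitude ``ranges`` = (lo, hi): m eigenvalues drawn
    uniformly in [-hi, -lo] and n - m in [lo, hi].
    """

    eigenvalues: tuple = None
    n: int = None
    m: int = None
    ranges: tuple = (0.5, 3.0)
    seed: int = 0

    def resolve(self) -> np.ndarray:
        if self.eigenvalues is not None:
            return np.sort(np.asarray(self.eigenvalues, dtype=float))
        if self.n is None or self.m is None:
            raise ValueError("provide either eigenvalues or (n, m)")
        lo, hi = self.ranges
        if not (0 < lo < hi):
            raise ValueError("ranges must satisfy 0 < lo < hi")
        rng = np.random.default_rng(self.seed)
        neg = -rng.uniform(lo, hi, size=self.m)
        pos = rng.uniform(lo, hi, size=self.n - self.m)
        return np.sort(np.concatenate([neg, pos]))


def random_orthonormal(n: int, seed: int) -> np.ndarray:
    """Seeded random orthonormal matrix: QR of a Gaussian draw, sign-fixed
    so the largest-magnitude entry of each column is positive."""
    rng = np.random.default_rng(seed)
    Q, R = np.linalg.qr(rng.standard_normal((n, n)))
    Q = Q * np.sign(np.diag(R))  # Haar-uniform up to sign
    idx = np.argmax(np.abs(Q), axis=0)
    signs = np.sign(Q[idx, np.arange(n)])
    signs[signs == 0] = 1.0
    return Q * signs


def make_spectrum_kernel(spec: SpectrumSpec) -> KernelMatrix:
    """Kernel ``P diag(d) P'`` with the requested eigenvalues and a seeded
    random orthonormal eigenbasis; ``decompose`` recovers the spectrum and
    inertia to 1e-8."""
    d = spec.resolve()
    P = random_orthonormal(d.size, spec.seed)
    return KernelMatrix((P * d) @ P.T, symmetrize=True)


def make_labeled_problem(
    n_per_class: int = 25,
    p: int = 5,
    separation: float = 2.0,
    nonneg: bool = False,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Two seeded unit-variance Gaussian clusters with mean separation
    ``separation`` along the first axis; labels are +/-1.  ``nonneg=True``
    shifts all features to be nonnegative (suitable for GHI kernels)."""
    if n_per_class < 5:
        raise ValueError("n_per_class must be >= 5")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_class, p))
    X[:n_per_class, 0] += separation / 2.0
    X[n_per_class:, 0] -= separation / 2.0
    y = np.concatenate([np.ones(n_per_class, int), -np.ones(n_per_class, int)])
    perm = rng.permutation(2 * n_per_class)
    X, y = X[perm], y[perm]
    if nonneg:
        X = X - X.min(axis=0, keepdims=True)
    return FeatureMatrix(X), y


def make_indefinite_problem(
    n_per_class: int = 25,
    p: int = 5,
    separation: float = 3.0,
    seed: int = 0,
) -> LabeledProblem:
    """A labeled problem with a typically indefinite cosine-of-distance kernel
    built from two Gaussian clusters; exercises the full rectify-then-classify
    pipeline on data with known class structure."""
    from .kernels import cosine_distance_gram

    X, y = make_labeled_problem(n_per_class, p, separation, seed=seed)
    return LabeledProblem(kernel=cosine_distance_gram(X), labels=y)
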