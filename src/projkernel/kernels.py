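"""Indefinite kernel constructions and q-gram count featurization.

Two similarity functions that typically produce indefinite Gram matrices:

* the generalized histogram intersection (GHI) kernel
  ``k(x, y) = sum_i min(|x_i|^alpha, |y_i|^beta)`` — PSD (and symmetric)
  when ``alpha == beta``, generally asymmetric and indefinite otherwise;
* the cosine-of-distance kernel ``k(x, y) = cos(||x - y||_2)`` — symmetric
  with unit diagonal but usually indefinite (distinct from the PSD cosine
  similarity ``x'y / (||x|| ||y||)``).

Sequence data enters through q-gram occurrence counts: each sample becomes
the vector of counts of every length-q substring observed in the collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .spectral import KernelMatrix, decompose, is_psd

__all__ = [
    "FeatureMatrix",
    "GHIParams",
    "QGramFeatures",
    "IndefinitenessReport",
    "ghi_gram",
    "cosine_distance_gram",
    "qgram_count_features",
    "indefiniteness_report",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Samples-by-attributes real matrix with identifiers."""

    values: np.ndarray
    sample_ids: tuple = None
    attribute_ids: tuple = None

    def __post_init__(self):
        arr = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature matrix contains non-finite entries")
        object.__setattr__(self, "values", arr)
        n, p = arr.shape
        if self.sample_ids is None:
            object.__setattr__(self, "sample_ids", tuple(f"s{i}" for i in range(n)))
        else:
            object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if self.attribute_ids is None:
            object.__setattr__(self, "attribute_ids", tuple(f"a{j}" for j in range(p)))
        else:
            object.__setattr__(self, "attribute_ids", tuple(self.attribute_ids))
        if len(self.sample_ids) != n or len(self.attribute_ids) != p:
            raise ValueError("identifier lengths do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GHIParams:
    """Exponents of the generalized histogram intersection kernel."""

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(f"GHI exponents must be positive, got alpha={self.alpha}, beta={self.beta}")


@dataclass(frozen=True)
class QGramFeatures:
    """q-gram occurrence counts for a sequence collection.

    ``vocabulary`` lists the distinct q-grams in first-occurrence order;
    ``counts[i, j]`` is the number of occurrences of ``vocabulary[j]`` in
    sequence i.  Row sums equal ``len(seq) - q + 1`` (zero for sequences
    shorter than q).
    """

    q: int
    vocabulary: tuple
    counts: np.ndarray

    def as_feature_matrix(self) -> FeatureMatrix:
        return FeatureMatrix(
            self.counts.astype(float), attribute_ids=self.vocabulary
        )


@dataclass(frozen=True)
class IndefinitenessReport:
    """One row of a kernel-definiteness survey."""

    label: str
    n: int
    min_eigenvalue: float
    neg_count: int
    psd: bool


def ghi_gram(
    X: FeatureMatrix | np.ndarray,
    params: GHIParams = GHIParams(),
    symmetrize: bool = True,
) -> KernelMatrix:
    """Generalized histogram intersection Gram matrix.

    Raw entry (j, k) is ``sum_i min(|X_ji|^alpha, |X_ki|^beta)``.  With
    ``alpha != beta`` the raw matrix is asymmetric; by default the
    symmetric part ``(K + K') / 2`` is returned.  With ``symmetrize=False``
    an asymmetric raw matrix is an error.
    """
    if not isinstance(X, FeatureMatrix):
        X = FeatureMatrix(X)
    A = np.abs(X.values) ** params.alpha  # rows indexed by j
    B = np.abs(X.values) ** params.beta  # rows indexed by k
    n, p = A.shape
    # K_raw[j, k] = sum_i min(A[j, i], B[k, i]); chunk rows to bound memory
    K_raw = np.empty((n, n))
    chunk = max(1, int(2e7 // max(n * p, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        K_raw[start:stop] = np.minimum(A[start:stop, None, :], B[None, :, :]).sum(axis=2)
    if symmetrize:
        return KernelMatrix(K_raw, symmetrize=True)
    return KernelMatrix(K_raw)  # raises if asymmetric beyond tolerance


def cosine_distance_gram(X: FeatureMatrix | np.ndarray) -> KernelMatrix:
    """Gram matrix of ``cos(||X_j - X_k||_2)``; unit diagonal, symmetric."""
    if not isinstance(X, FeatureMatrix):
        X = FeatureMatrix(X)
    D = squareform(pdist(X.values, metric="euclidean"))
    K = np.cos(D)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, symmetrize=True)


def qgram_count_features(sequences, q: int) -> QGramFeatures:
    """Count length-q substrings across a sequence collection.

    The vocabulary is the set of all q-grams occurring anywhere in the
    collection, ordered by first occurrence (scanning sequences in order,
    positions left to right); kernel values are invariant to this order.
    """
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    sequences = [str(s) for s in sequences]
    vocab: dict[str, int] = {}
    rows = []
    for seq in sequences:
        counts: dict[int, int] = {}
        for start in range(len(seq) - q + 1):
            gram = seq[start : start + q]
            j = vocab.setdefault(gram, len(vocab))
            counts[j] = counts.get(j, 0) + 1
        rows.append(counts)
    mat = np.zeros((len(sequences), len(vocab)), dtype=int)
    for i, counts in enumerate(rows):
        for j, c in counts.items():
            mat[i, j] = c
    return QGramFeatures(q=q, vocabulary=tuple(vocab), counts=mat)


def indefiniteness_report(
    K: KernelMatrix | np.ndarray, label: str = "", tol_rel: float = 1e-8
) -> IndefinitenessReport:
    """Summarize a kernel's definiteness: size, smallest eigenvalue, inertia."""
    if not isinstance(K, KernelMatrix):
        K = KernelMatrix(K)
    decomp = decompose(K, tol_rel=tol_rel)
    psd, min_eig = is_psd(K, tol_rel=tol_rel)
    return IndefinitenessReport(
        label=label,
        n=K.n,
        min_eigenvalue=min_eig,
        neg_count=decomp.neg_index,
        psd=psd,
    )
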