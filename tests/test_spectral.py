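"""Eigendecomposition conventions, the projection transform and its special cases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from projkernel import (
    KernelMatrix,
    SpectrumSpec,
    decompose,
    denoise_kernel,
    flip_kernel,
    is_psd,
    make_spectrum_kernel,
    project_kernel,
    projection_factor,
)

from conftest import random_symmetric


class TestKernelMatrix:
    def test_rejects_asymmetry_and_names_it(self):
        A = np.array([[1.0, 0.5], [0.1, 1.0]])
        with pytest.raises(ValueError, match="not symmetric"):
            KernelMatrix(A)
        K = KernelMatrix(A, symmetrize=True)
        np.testing.assert_allclose(K.values, (A + A.T) / 2)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            KernelMatrix(np.zeros((2, 3)))


class TestDecompose:
    def test_inertia_on_diagonal_spectrum(self):
        d = decompose(KernelMatrix(np.diag([-1.0, 2.0])))
        assert (d.neg_index, d.zero_count, d.pos_index) == (1, 0, 1)
        np.testing.assert_allclose(d.eigenvalues, [-1.0, 2.0])

    def test_identity_has_no_negatives(self):
        d = decompose(KernelMatrix(np.eye(3)))
        assert d.neg_index == 0 and d.pos_index == 3
        np.testing.assert_allclose(d.eigenvalues, np.ones(3))

    def test_reconstruction_and_orthonormality(self, rng):
        K = KernelMatrix(random_symmetric(rng, 8))
        d = decompose(K)
        P = d.eigenvectors
        np.testing.assert_allclose(P.T @ P, np.eye(8), atol=1e-8)
        np.testing.assert_allclose((P * d.eigenvalues) @ P.T, K.values, atol=1e-8)
        assert np.all(np.diff(d.eigenvalues) >= 0)
        assert d.neg_index + d.zero_count + d.pos_index == 8

    def test_sign_convention_is_deterministic(self, rng):
        K = KernelMatrix(random_symmetric(rng, 6))
        d1, d2 = decompose(K), decompose(K)
        np.testing.assert_array_equal(d1.eigenvectors, d2.eigenvectors)
        idx = np.argmax(np.abs(d1.eigenvectors), axis=0)
        assert np.all(d1.eigenvectors[idx, np.arange(6)] > 0)

    def test_zero_eigenvalues_not_counted_negative(self):
        d = decompose(KernelMatrix(np.diag([0.0, 1.0, 2.0])))
        assert d.neg_index == 0 and d.zero_count == 1


class TestProjectionFactor:
    def test_spectrum_multiplicities(self):
        K = make_spectrum_kernel(SpectrumSpec(eigenvalues=(-1.0, 2.0), seed=1))
        F = projection_factor(decompose(K), lam=2.0)
        np.testing.assert_allclose(np.linalg.eigvalsh(F.values), [-1.0, 1.0], atol=1e-8)

    def test_identity_when_psd(self, psd_kernel):
        F = projection_factor(decompose(psd_kernel), lam=7.3)
        np.testing.assert_array_equal(F.values, np.eye(psd_kernel.n))

    def test_lemma_multiplicities_by_independent_eigensolve(self):
        K = make_spectrum_kernel(SpectrumSpec(n=10, m=4, seed=3))
        F = projection_factor(decompose(K), lam=1.5)
        eigs = np.sort(np.linalg.eigvalsh(F.values))
        expected = np.sort([-0.5] * 4 + [1.0] * 6)
        np.testing.assert_allclose(eigs, expected, atol=1e-8)

    def test_commutes_with_kernel(self):
        K = make_spectrum_kernel(SpectrumSpec(n=9, m=3, seed=5))
        F = projection_factor(decompose(K), lam=1.7).values
        np.testing.assert_allclose(F @ K.values, K.values @ F, atol=1e-8)


class TestProjectKernel:
    @pytest.mark.parametrize(
        "lam, expected",
        [(2.0, [1.0, 2.0]), (1.0, [0.0, 2.0])],
        ids=["flip", "clip"],
    )
    def test_two_eigenvalue_special_cases(self, lam, expected):
        K = make_spectrum_kernel(SpectrumSpec(eigenvalues=(-1.0, 2.0), seed=2))
        out = project_kernel(K, lam)
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvalsh(out.transformed.values)), expected, atol=1e-10
        )

    def test_negative_lam_rejected(self, indefinite_kernel):
        with pytest.raises(ValueError, match="lam"):
            project_kernel(indefinite_kernel, -0.1)

    def test_psd_input_returned_exactly(self, psd_kernel):
        out = project_kernel(psd_kernel, 13.7)
        assert out.transformed.values is psd_kernel.values
        assert out.psd_certified

    def test_psd_certificate_over_lambda_range(self, rng):
        # Monte-Carlo: projection at any lam >= 1 yields a certified PSD kernel
        for _ in range(50):
            n = int(rng.integers(4, 12))
            K = KernelMatrix(random_symmetric(rng, n))
            lam = float(rng.uniform(1.0, 200.0))
            out = project_kernel(K, lam)
            assert out.psd_certified
            ok, _ = is_psd(out.transformed)
            assert ok

    def test_matches_factor_product(self, indefinite_kernel):
        # eigenbasis rebuild agrees with the explicit (I - lam BB')K product
        lam = 1.8
        d = decompose(indefinite_kernel)
        F = projection_factor(d, lam).values
        out = project_kernel(indefinite_kernel, lam).transformed.values
        np.testing.assert_allclose(out, (F @ indefinite_kernel.values + indefinite_kernel.values @ F) / 2, atol=1e-8)


class TestDenoiseFlip:
    def test_denoise_clips_spectrum(self):
        K = make_spectrum_kernel(SpectrumSpec(eigenvalues=(-3.0, -1.0, 2.0), seed=4))
        out = denoise_kernel(K)
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvalsh(out.transformed.values)), [0.0, 0.0, 2.0], atol=1e-10
        )

    def test_flip_takes_absolute_spectrum(self):
        K = make_spectrum_kernel(SpectrumSpec(eigenvalues=(-3.0, -1.0, 2.0), seed=4))
        out = flip_kernel(K)
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvalsh(out.transformed.values)), [1.0, 2.0, 3.0], atol=1e-10
        )

    def test_denoise_equals_independent_spectral_clip(self, rng):
        K = KernelMatrix(random_symmetric(rng, 9))
        d, P = np.linalg.eigh(K.values)  # independent clip oracle
        clip = (P * np.clip(d, 0.0, None)) @ P.T
        np.testing.assert_allclose(denoise_kernel(K).transformed.values, clip, atol=1e-10)

    def test_delegates_match_project(self, indefinite_kernel):
        np.testing.assert_allclose(
            denoise_kernel(indefinite_kernel).transformed.values,
            project_kernel(indefinite_kernel, 1.0).transformed.values,
            atol=1e-10,
        )
        np.testing.assert_allclose(
            flip_kernel(indefinite_kernel).transformed.values,
            project_kernel(indefinite_kernel, 2.0).transformed.values,
            atol=1e-10,
        )


class TestIsPsd:
    def test_identity(self):
        ok, min_eig = is_psd(KernelMatrix(np.eye(4)))
        assert ok and min_eig == pytest.approx(1.0)

    def test_slightly_indefinite_flagged(self):
        # mirrors the near-PSD case: smallest eigenvalue -0.08 fails the check
        K = make_spectrum_kernel(SpectrumSpec(eigenvalues=(-0.08, 1.0, 2.0, 3.0), seed=6))
        ok, min_eig = is_psd(K)
        assert not ok and min_eig == pytest.approx(-0.08, abs=1e-8)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    A=arrays(np.float64, (6, 6), elements=st.floats(-5, 5, allow_nan=False)),
    lam=st.floats(1.0, 200.0),
)
def test_projection_always_psd_for_lam_ge_one(A, lam):
    """Any symmetric matrix projected at lam >= 1 certifies PSD."""
    K = KernelMatrix((A + A.T) / 2)
    out = project_kernel(K, lam)
    assert out.psd_certified
    scale = max(np.max(np.abs(np.linalg.eigvalsh(K.values))), 1.0)
    assert out.min_eigenvalue >= -1e-8 * scale
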