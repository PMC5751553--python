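import numpy as np
import pytest

from projkernel import SpectrumSpec, make_spectrum_kernel


@pytest.fixture
def indefinite_kernel():
    """8x8 kernel with 3 negative eigenvalues, fixed seed."""
    return make_spectrum_kernel(
        SpectrumSpec(eigenvalues=(-2.0, -1.0, -0.5, 0.8, 1.5, 2.0, 3.0, 4.0), seed=42)
    )


@pytest.fixture
def psd_kernel():
    return make_spectrum_kernel(SpectrumSpec(eigenvalues=(0.5, 1.0, 2.0, 3.0, 5.0), seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_symmetric(rng, n):
    A = rng.standard_normal((n, n))
    return (A + A.T) / 2.0
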