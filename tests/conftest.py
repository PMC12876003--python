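import numpy as np
import pytest

from danpv.framework import case_framework, make_framework


@pytest.fixture(scope="session")
def qianshan():
    """The bundled 6-dimension / 16-criterion case framework."""
    return case_framework()


@pytest.fixture
def tiny_framework():
    """Two dimensions, four criteria: small enough for hand arithmetic."""
    return make_framework({"DA": ["A1", "A2"], "DB": ["B1", "B2"]})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_substochastic(rng, n, row_cap=0.9):
    """Random nonnegative matrix with row sums <= row_cap (spectral radius < 1)."""
    m = rng.random((n, n))
    np.fill_diagonal(m, 0.0)
    scale = row_cap / m.sum(axis=1).max()
    return m * scale
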