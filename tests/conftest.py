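import numpy as np
import pytest

from tailorcut import ParameterSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pop5():
    """Standardized 5-item one-factor population (loadings .8..(-.05)..0.6)."""
    loadings = np.array([0.80, 0.75, 0.70, 0.65, 0.60])
    return ParameterSet(loadings.reshape(-1, 1), np.eye(1),
                        np.diag(1 - loadings**2),
                        [f"x{i}" for i in range(1, 6)], ["f1"])


@pytest.fixture
def model5_text():
    return "f1 =~ x1 + x2 + x3 + x4 + x5"


def random_covariance(rng, p, n_base=200):
    """Random well-conditioned covariance matrix (Wishart-style)."""
    a = rng.standard_normal((n_base, p))
    return a.T @ a / n_base
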