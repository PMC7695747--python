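import numpy as np
import pytest

from qae.encoding import QuboProblem


def make_random_qubo(seed: int, m: int, scale: float = 1.0) -> QuboProblem:
    """Seeded dense random QUBO with coefficients uniform in [-scale, scale]."""
    rng = np.random.default_rng(seed)
    return QuboProblem(coeffs=np.triu(rng.uniform(-scale, scale, (m, m))))


def make_random_symmetric(seed: int, n: int, scale: float = 1.0) -> np.ndarray:
    """Seeded random symmetric matrix with entries uniform in [-scale, scale]."""
    rng = np.random.default_rng(seed)
    m = rng.uniform(-scale, scale, (n, n))
    return (m + m.T) / 2.0


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
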