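import numpy as np
import pytest

from capcri.types import SignalSegment


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def sinusoid_resp():
    """120-s pure 0.25 Hz sinusoid sampled at 10 Hz."""
    t = np.arange(0, 120, 0.1)
    return SignalSegment(np.sin(2 * np.pi * 0.25 * t), 10.0, 0.0, "resp")


def simulate_var(coeffs, sigma, T, rng, burn=200):
    """Simulate a bivariate VAR given lag matrices and innovation cov."""
    p = len(coeffs)
    y = np.zeros((T + burn, 2))
    eps = rng.multivariate_normal([0.0, 0.0], sigma, size=T + burn)
    for t in range(p, T + burn):
        acc = eps[t].copy()
        for j, A in enumerate(coeffs, start=1):
            acc += A @ y[t - j]
        y[t] = acc
    return y[burn:]


@pytest.fixture
def var2_known():
    """A strongly autocorrelated, stable VAR(2) used for recovery tests."""
    A1 = np.array([[0.0, 0.10], [0.05, 0.0]])
    A2 = np.array([[-0.95, 0.0], [0.0, -0.92]])
    sigma = np.array([[1.0, 0.2], [0.2, 1.0]])
    return (A1, A2), sigma
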