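import numpy as np
import pytest
from scipy.stats import vonmises

TWO_PI = 2.0 * np.pi


def vm_draw(rng, mu, kappa, n):
    """Wrapped von Mises draws in [0, 2*pi)."""
    return np.mod(rng.vonmises(mu, kappa, size=n), TWO_PI)


def delta_quadrature(k1, m1, k2, m2, n_points=100_001):
    """Oracle: trapezoid of min of two closed-form von Mises densities."""
    g = np.linspace(0.0, TWO_PI, n_points)
    f1 = vonmises(k1, loc=m1).pdf(g)
    f2 = vonmises(k2, loc=m2).pdf(g)
    return float(np.trapezoid(np.minimum(f1, f2), g))


@pytest.fixture
def rng():
    return np.random.default_rng(20230715)
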