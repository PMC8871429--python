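import numpy as np
import pytest

from gelosmo import GelModel, WATER_25C


@pytest.fixture
def solvent():
    return WATER_25C


@pytest.fixture
def simple_gel():
    """A plain swollen-gel model: repulsive virials plus a 10 kPa network."""
    return GelModel(A2=0.05, A3=0.3, elastic_C=10_000.0, phi_ref=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_roots(model, phi_min=1e-4, phi_max=0.99, n=1_000_000):
    """Dense-scan oracle for the equilibria of Pi_tot(phi) = 0.

    Vectorised sign-change count on a log grid, independent of the package's
    coarse-scan + bisection path.
    """
    grid = np.logspace(np.log10(phi_min), np.log10(phi_max), n)
    f = np.asarray(model.swelling_pressure(grid))
    s = np.sign(f)
    idx = np.nonzero(s[1:] * s[:-1] < 0)[0]
    # bracket midpoints, accurate to one grid step
    return 0.5 * (grid[idx] + grid[idx + 1]), grid[1] / grid[0] - 1.0
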