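import numpy as np
import pytest

from idpchar import synthetic
from idpchar.saxs import SAXSCurve


@pytest.fixture(scope="session")
def s_grid():
    """Default measurement grid: 200 log-spaced points, 0.0025-0.441 A^-1."""
    return np.geomspace(0.0025, 0.441, 200)


@pytest.fixture(scope="session")
def sphere_curve(s_grid):
    """Noiseless homogeneous-sphere curve, R = 30 A."""
    return SAXSCurve(s=s_grid, intensity=synthetic.sphere_intensity(s_grid, 30.0),
                     label="sphere R=30")


@pytest.fixture(scope="session")
def debye_curve(s_grid):
    """Noiseless Gaussian-chain curve, Rg = 50 A."""
    return SAXSCurve(s=s_grid, intensity=synthetic.debye_function(s_grid, 50.0),
                     label="debye Rg=50")


@pytest.fixture(scope="session")
def cd_basis():
    return synthetic.reference_cd_basis()


@pytest.fixture(scope="session")
def small_pool():
    """Shared 300-conformer pool of 60-residue chains (session-cached)."""
    from idpchar import ensemble
    return ensemble.generate_pool(60, 300, seed=2)
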