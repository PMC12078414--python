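import numpy as np
import pytest

from ccrama import physmodel as pm
from ccrama import synthgen as sg


@pytest.fixture(scope="session")
def surfaces_1deg():
    """Amplitude surfaces for all ten kinds at the working 1 deg resolution."""
    return pm.build_rate_surfaces(resolution=1.0)


@pytest.fixture(scope="session")
def surfaces_10deg():
    return pm.build_rate_surfaces(resolution=10.0)


@pytest.fixture(scope="session")
def remote_surfaces_1deg(surfaces_1deg):
    return {rid: surfaces_1deg[rid] for rid in pm.REMOTE_RATE_IDS}


@pytest.fixture(scope="session")
def coil_prior_1deg():
    return sg.standin_coil_prior(1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_unit_vectors(rng, n):
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
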