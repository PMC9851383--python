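import numpy as np
import pytest

from cryptsim.crypt import CryptGeometry, GradientParams, init_crypt, step_crypt


@pytest.fixture(scope="session")
def gradients():
    return GradientParams()


@pytest.fixture(scope="session")
def tiny_geometry():
    """A very small crypt for fast dynamical tests."""
    return CryptGeometry(
        circumference=5, height=10, homeostatic_target=48, min_viable_cells=38
    )


@pytest.fixture(scope="session")
def reduced_geometry():
    return CryptGeometry.reduced()


@pytest.fixture
def settled_tiny_crypt(tiny_geometry, gradients):
    """A tiny crypt run to its stationary state."""
    state = init_crypt(tiny_geometry, gradients, seed=11)
    for _ in range(150):
        step_crypt(state)
    return state


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
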