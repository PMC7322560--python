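import numpy as np
import pytest

from lcmvbench import SphereModel, build_grid, build_helmet_array


@pytest.fixture(scope="session")
def sphere():
    return SphereModel(conductor_radius=0.09)


@pytest.fixture(scope="session")
def small_array():
    """12-channel triple-sensor array: cheap but structurally complete."""
    return build_helmet_array(n_sites=4)


@pytest.fixture(scope="session")
def medium_array():
    """36-channel array for covariance/beamformer tests."""
    return build_helmet_array(n_sites=12)


@pytest.fixture(scope="session")
def coarse_grid(sphere):
    """10-mm upper-half grid: ~1200 points, fast to scan."""
    return build_grid(sphere, spacing=0.01, inside_margin=0.0075,
                      region="upper_half")


@pytest.fixture()
def rng():
    return np.random.default_rng(4242)
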