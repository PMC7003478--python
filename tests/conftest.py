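import numpy as np
import pytest

from parcelbundle import phantom
from parcelbundle.parcellation import build_distance_fields


@pytest.fixture(scope="session")
def small_phantom():
    """A compact separable phantom: 6 ROIs, 4 bundles, 48 fibers."""
    return phantom.make_phantom(
        grid=40, L=6, K=4, n_per_bundle=12, point_noise=0.6,
        terminal_jitter=0.5, roi_radius=3.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_dist(small_phantom):
    return build_distance_fields(small_phantom.parcellation)


@pytest.fixture(scope="session")
def default_phantom():
    return phantom.make_phantom(seed=5)


@pytest.fixture(scope="session")
def default_dist(default_phantom):
    return build_distance_fields(default_phantom.parcellation)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
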