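import numpy as np
import pytest

import cortmatch as cm


@pytest.fixture(scope="session")
def sphere60():
    """Small sphere geometry for cheap unit tests."""
    return cm.make_sphere_geometry(60, 80.0)


@pytest.fixture(scope="session")
def sphere180():
    """Study-scale geometry: 180 parcels on an 80 mm sphere."""
    return cm.make_sphere_geometry(180, 80.0)


@pytest.fixture(scope="session")
def grf180(sphere180):
    """Cached GRF sampler at the default correlation length (30 mm)."""
    return cm.GRFSampler(sphere180, cm.GRFParams(range_mm=30.0))


@pytest.fixture(scope="session")
def toy_volumes():
    """(parcel atlas, group atlas, stat points) hand-checkable fixture."""
    return cm.make_toy_volume_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
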