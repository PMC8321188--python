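import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mwbreast as mw

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_array():
    """6 antennas in one ring: 6-fold symmetry, 60 degree step."""
    return mw.build_array(6, 0.07, ((60.0, 6),))


@pytest.fixture(scope="session")
def ring10_array():
    """Single-ring 10-antenna array: 36 degree step."""
    return mw.build_array(10, 0.07, ((60.0, 10),))


@pytest.fixture(scope="session")
def array24():
    return mw.ARRAY_PRESETS["rings24"]()


@pytest.fixture(scope="session")
def freqs5():
    return mw.FrequencyGrid.default(5)


@pytest.fixture(scope="session")
def freqs21():
    return mw.FrequencyGrid.default(21)


@pytest.fixture(scope="session")
def coarse_grid():
    """1 cm voxels over the 7 cm hemisphere (~700 voxels)."""
    return mw.ImagingGrid.build(spacing=0.01)


@pytest.fixture(scope="session")
def grid5mm():
    return mw.ImagingGrid.build(spacing=0.005)


def random_scan(array, freqs, seed, nch_data_scale=1.0):
    """Random dense complex scan on all bistatic channels (test helper)."""
    channels = mw.bistatic_channels(array.n_antennas)
    rng = np.random.default_rng(seed)
    data = nch_data_scale * (
        rng.standard_normal((channels.shape[0], freqs.n_points))
        + 1j * rng.standard_normal((channels.shape[0], freqs.n_points))
    )
    return mw.MultistaticScan(
        data=data,
        channels=channels,
        frequencies=freqs.frequencies,
        array=array,
        meta={"history": []},
    )
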