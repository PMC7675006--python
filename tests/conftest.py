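import numpy as np
import pytest

import hsical as h


@pytest.fixture(scope="session")
def fw_bandset():
    return h.load_band_table("filter_wheel")


@pytest.fixture(scope="session")
def c44_bandset():
    return h.load_band_table("cam4x4")


@pytest.fixture(scope="session")
def c55_bandset():
    return h.load_band_table("cam5x5")


@pytest.fixture(scope="session")
def dual_bandset(c44_bandset, c55_bandset):
    return h.concat_bandsets(c44_bandset, c55_bandset)


@pytest.fixture(scope="session")
def chart():
    return h.make_reference_chart(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def smooth_image():
    """A smooth, textured test image with nonzero variance everywhere."""
    g = np.random.default_rng(7).normal(0, 1, (64, 64))
    img = g.cumsum(axis=0).cumsum(axis=1)
    return (img - img.min()) / np.ptp(img) + 0.1
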