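import numpy as np
import pytest

from coralhue.iscc_nbs import load_iscc_table


@pytest.fixture(scope="session")
def iscc_table():
    return load_iscc_table()


@pytest.fixture(scope="session")
def srgb_table():
    """Table configured for plain sRGB-Euclidean matching."""
    return load_iscc_table(colour_space_for_matching="srgb")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
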