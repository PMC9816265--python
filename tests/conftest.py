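import numpy as np
import pytest

from nsctfuse import build_fan_filters, build_pyramid_filters


@pytest.fixture(scope="session")
def pyr_bank():
    return build_pyramid_filters("pyrexc")


@pytest.fixture(scope="session")
def fan_bank():
    return build_fan_filters("vk")


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def random_image(rng):
    return rng.random((32, 32))
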