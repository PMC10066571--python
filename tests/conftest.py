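import numpy as np
import pytest

from auderp import fibonacci_montage
from auderp.simulate import GroupProfile, NoiseSpec, default_profiles


@pytest.fixture(scope="session")
def layout128():
    return fibonacci_montage(128)


@pytest.fixture(scope="session")
def layout32():
    return fibonacci_montage(32)


@pytest.fixture(scope="session")
def layout8():
    return fibonacci_montage(8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def silent_control() -> GroupProfile:
    """CONTROL component profile with every noise source switched off."""
    prof = default_profiles()["CONTROL"]
    prof.noise = NoiseSpec(0.0, 0.0, 0.0, 0.0, 0.0)
    return prof
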