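import numpy as np
import pytest

from kinemetry import CameraIntrinsics
from kinemetry.synthetic import default_template


@pytest.fixture
def intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(f=525.0, xo=319.5, yo=239.5, width=640, height=480)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def template():
    return default_template()
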