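import numpy as np
import pytest

from stridekit.segmentation import default_template, default_threshold
from stridekit.synth import StrideSpec, synthesize_walk

PD_SPEC = StrideSpec(
    stride_length=1.15,
    stride_time=1.10,
    stance_fraction=0.650,
    max_clearance=0.106,
    hs_angle=19.0,
    to_angle=-54.8,
)
CONTROL_SPEC = StrideSpec()  # control-group defaults


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def threshold():
    return default_threshold()


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free 4×8-stride walk with 3 turns (one foot)."""
    walks = synthesize_walk(
        CONTROL_SPEC, n_strides_per_bout=8, seed=7, noise_sd=(0.0, 0.0), sides=("left",)
    )
    return walks["left"]


@pytest.fixture(scope="session")
def noisy_walk():
    """Default-noise 4×8-stride walk with 3 turns (one foot)."""
    walks = synthesize_walk(CONTROL_SPEC, n_strides_per_bout=8, seed=7, sides=("left",))
    return walks["left"]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
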