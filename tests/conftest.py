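import numpy as np
import pytest

from neurophenoclust.synthetic_data import (
    default_head_spec,
    make_head_phantom,
    make_lesion_phantom,
)


@pytest.fixture(scope="session")
def ball_phantom():
    """Digital ball, r = 10 mm on a 1 mm isotropic grid, with truth."""
    return make_lesion_phantom("ball", radius=10.0)


@pytest.fixture(scope="session")
def head_phantom():
    """Default whole-head phantom with one periventricular and two deep WMH."""
    spec = default_head_spec(seed=7)
    seg, truth, lobe_map = make_head_phantom(spec)
    return spec, seg, truth, lobe_map


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
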