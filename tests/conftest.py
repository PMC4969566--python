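import numpy as np
import pytest

from eegkappa import SynthSpec, generate_segment


@pytest.fixture
def rng():
    return np.random.default_rng(20160719)


@pytest.fixture
def ramp_segment():
    """60 s unit-slope ramp at 250 Hz: every kappa is exactly 1."""
    return generate_segment(SynthSpec(kind="ramp", params={"slope": 1.0}))


@pytest.fixture
def white_noise_segment():
    """60 s of iid N(0,1) samples at 250 Hz."""
    return generate_segment(
        SynthSpec(kind="white_noise", params={"sigma": 1.0}, seed=7)
    )
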