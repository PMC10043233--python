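import numpy as np
import pytest

from stopnet import synth


@pytest.fixture(scope="session")
def small_protocol() -> synth.ProtocolSpec:
    """A scaled-down treadmill-style protocol for fast structural tests."""
    return synth.ProtocolSpec.preset(
        "treadmill", n_trials=2, reps_per_trial=2, trial_len_s=30.0, lead_in_s=3.0
    )


@pytest.fixture(scope="session")
def small_session(small_protocol) -> synth.SyntheticSession:
    return synth.generate_session(small_protocol, seed=7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
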