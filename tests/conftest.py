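import numpy as np
import pytest

from gpcrswitch.synth import gen_switch_bundle, marker_topology


@pytest.fixture(scope="session")
def marker_top():
    return marker_topology()


@pytest.fixture(scope="session")
def small_bundle():
    """A short marker trajectory shared by tests that only need plumbing."""
    return gen_switch_bundle(n_frames=300, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
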