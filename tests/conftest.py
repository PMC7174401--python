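import numpy as np
import pytest

from chromorheo import make_fixture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def drifting_bundle():
    """Noise-free drifting preset: rendered stack + ground truth."""
    return make_fixture("drifting")


@pytest.fixture(scope="session")
def confined_bundle():
    return make_fixture("confined_voigt")
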