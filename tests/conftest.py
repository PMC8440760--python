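import warnings

import numpy as np
import pytest

from mammosub.phantom import PhantomSpec, make_phantom_pair

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_pair():
    """One default phantom pair shared across tests (seed 0)."""
    return make_phantom_pair(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def clean_pair():
    """Phantom pair with no deformation, noise or drift: prior equals
    recent minus the new findings exactly."""
    return make_phantom_pair(
        PhantomSpec(seed=3, deformation_amplitude_px=0, noise_sigma=0, drift_amplitude=0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
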