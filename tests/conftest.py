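import numpy as np
import pytest

import funcgrad as fg


@pytest.fixture(scope="session")
def geometry():
    """Small fixed geometry shared by read-only tests."""
    return fg.make_latent_geometry(70, 2, 0.4, seed=1)


@pytest.fixture(scope="session")
def design():
    return fg.StudyDesign()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
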