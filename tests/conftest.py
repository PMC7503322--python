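import warnings

import numpy as np
import pytest

from triadsim.config import build_study_config

# the pseudo-yoking cap clamp warns by design; tests that exercise it opt in
warnings.filterwarnings("ignore", message=".*pseudo-yoked duration.*")


@pytest.fixture(scope="session")
def study1_config():
    return build_study_config(1)


@pytest.fixture(scope="session")
def study2_config():
    return build_study_config(2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
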