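import numpy as np
import pytest

from stochtex import FilterbankConfig, TextureParams


@pytest.fixture(scope="session")
def fb():
    """Default auditory-model configuration."""
    return FilterbankConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160301)


@pytest.fixture(scope="session")
def standard_params():
    """Standard stimulus of the modulation-gain discrimination condition."""
    return TextureParams(A=1.0, B=1.5, f0=34.0, C=0.5, duration=1.0, seed=101)


@pytest.fixture(scope="session")
def standard_token(standard_params):
    from stochtex import synthesize

    return synthesize(standard_params)
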