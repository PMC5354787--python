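import pytest

from cea_nsclc import build_default_registry
from cea_nsclc.markov import ModelConfig


@pytest.fixture(scope="session")
def reg():
    return build_default_registry()


@pytest.fixture(scope="session")
def cfg():
    return ModelConfig()
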