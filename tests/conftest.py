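import pytest

from famscan.motifs import stringent_pattern
from famscan.synth import SyntheticConfig


@pytest.fixture(scope="session")
def stringent():
    return stringent_pattern()


@pytest.fixture
def config():
    return SyntheticConfig(seed=0)
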