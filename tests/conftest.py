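import numpy as np
import pytest

from evocompass.fixtures import toy_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy():
    """Fixed 12-variant, 3-block dataset."""
    return toy_fixture()
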