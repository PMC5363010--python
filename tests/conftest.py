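import numpy as np
import pytest

from hemescan.reference_model import default_reference


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_000)
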