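import numpy as np
import pytest

from mcse import worked_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """The library of hand-checked toy graphs."""
    return worked_fixtures()


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
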