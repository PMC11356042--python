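import numpy as np
import pytest

from magsense.config import default_config
from magsense.transport import build_field_table


@pytest.fixture(scope="session")
def r500():
    return default_config("R500")


@pytest.fixture(scope="session")
def r2000():
    return default_config("R2000")


@pytest.fixture(scope="session")
def r500_table(r500):
    # module-level cache makes this cheap to share across test modules
    return build_field_table(r500)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240723)
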