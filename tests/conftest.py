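import numpy as np
import pytest

from dnafcm.competition import CompetitionConfig
from dnafcm.synthetic import iid_fixture


@pytest.fixture(scope="session")
def small_cfg():
    """Cheap config used where the default depth set would be overkill."""
    return CompetitionConfig(depths=(2, 4, 8, 12), block_size=100)


@pytest.fixture(scope="session")
def iid_10k():
    return iid_fixture(10_000, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
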