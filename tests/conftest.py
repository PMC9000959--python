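import numpy as np
import pytest

from yeastcons.library import StrainLibrary, default_library


@pytest.fixture(scope="session")
def library() -> StrainLibrary:
    return default_library()


@pytest.fixture(scope="session")
def iaa_sensor(library):
    """Auxin-repressed GFP sensor used as the standard readout strain."""
    return library["IAA_rep_GFP"]


@pytest.fixture(scope="session")
def small_pool(library):
    """Four-strain pool for exhaustive small-instance screens."""
    return [library[s] for s in
            ["aF_rep_IAA", "bE_rep_IAA", "aF_act_IAA", "bE_act_IAA"]]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
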