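import numpy as np
import pytest
from hypothesis import settings

from dpdchem.beads import default_library
from dpdchem.params import build_paramset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def water_params(library):
    """Parameter set for a pure-solvent box."""
    return build_paramset(library, [])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210413)
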