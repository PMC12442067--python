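import pytest

from pyreneclar import molecules as M
from pyreneclar.synthetic_data import EnumerationSpec, enumerate_space, sample_strain_set


@pytest.fixture(scope="session")
def references():
    """Small named reference PBHs."""
    return {
        "benzene": M.benzene(),
        "naphthalene": M.naphthalene(),
        "anthracene": M.anthracene(),
        "phenanthrene": M.phenanthrene(),
        "triphenylene": M.triphenylene(),
        "benzo[c]phenanthrene": M.benzo_c_phenanthrene(),
        "pyrene": M.pyrene(),
        "hexahelicene": M.hexahelicene(),
    }


@pytest.fixture(scope="session")
def sample_set():
    """The 13-molecule strain sample set."""
    return sample_strain_set()


@pytest.fixture(scope="session")
def small_space():
    """The 5-7-ring slice of the pyrene chemical space."""
    return enumerate_space(EnumerationSpec(5, 7))


@pytest.fixture(scope="session")
def full_space():
    """The complete 5-10-ring pyrene chemical space."""
    return enumerate_space(EnumerationSpec(5, 10))
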