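import numpy as np
import pytest

from pectolyze.composition import enumerate_library, load_reference_library, reference_library_table


@pytest.fixture(scope="session")
def reference_table():
    return reference_library_table()


@pytest.fixture(scope="session")
def reference_library():
    return load_reference_library()


@pytest.fixture(scope="session")
def enumerated_library():
    return enumerate_library((2, 8), 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
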