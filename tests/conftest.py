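import numpy as np
import pytest

from mitopsi import synthetic as syn


@pytest.fixture(scope="session")
def library():
    lib, _ = syn.make_reference_library()
    return lib


@pytest.fixture(scope="session")
def library_info():
    _, info = syn.make_reference_library()
    return info


@pytest.fixture(scope="session")
def mb_library():
    lib, _ = syn.make_reference_library(include_myoglobin=True)
    return lib


@pytest.fixture(scope="session")
def true_curve():
    return syn.default_true_curve()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
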