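import logging

import numpy as np
import pytest

import croaker as ck

logging.getLogger("croaker").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def mother():
    return ck.build_mother_wavelet(8)


@pytest.fixture(scope="session")
def mother_fast():
    """Coarser wavelet for speed-insensitive shape tests."""
    return ck.build_mother_wavelet(6)


@pytest.fixture(scope="session")
def reference_spec():
    return ck.reference_call_spec()


@pytest.fixture(scope="session")
def reference_call(mother, reference_spec):
    return ck.synthesize_call(reference_spec, mother).peak_normalized()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
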