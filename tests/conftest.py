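import numpy as np
import pytest

from methylfp import make_assay_presets


@pytest.fixture(scope="session")
def presets():
    return make_assay_presets()


@pytest.fixture(scope="session")
def dnmt1(presets):
    return presets["DNMT1"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
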