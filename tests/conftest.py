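import numpy as np
import pytest

from cyclokit import CDBuildParams, build_cd_frame


@pytest.fixture(scope="session")
def ideal_cd():
    """Noise-free 7-unit host frame and its topology."""
    return build_cd_frame(CDBuildParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
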