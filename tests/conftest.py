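import logging

import numpy as np
import pytest

from cellmech.physics import ProbeSpec

# cell-exclusion messages are expected in bulk-pipeline tests
logging.getLogger("cellmech.forcecurve").setLevel(logging.ERROR)


@pytest.fixture
def probe() -> ProbeSpec:
    return ProbeSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
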