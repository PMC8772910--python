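import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from thermotex.study_design import reference_horses, reference_riders


@pytest.fixture(scope="session")
def reference_cohort():
    """The published six riders and twelve horses."""
    return reference_riders(), reference_horses()


@pytest.fixture
def rng():
    return np.random.default_rng(20220113)


def random_plane(rng, shape=(16, 16), bits=8):
    return rng.integers(0, 1 << bits, size=shape, dtype=np.int64)
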