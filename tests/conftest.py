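import numpy as np
import pytest

import dnatwin as dt


@pytest.fixture(scope="session")
def small_refs() -> dt.ReferencePool:
    """20 random 60-mers; small enough for exhaustive alignment checks."""
    return dt.generate_reference_pool(20, 60, seed=101)


@pytest.fixture(scope="session")
def refs_150() -> dt.ReferencePool:
    """200 random 150-mers, the standard payload geometry."""
    return dt.generate_reference_pool(200, 150, seed=202)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
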