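import numpy as np
import pytest

from stemver import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_spec():
    """A quick cohort at the default (published-summary) distributions."""
    return CohortSpec(n=500, seed=7)
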