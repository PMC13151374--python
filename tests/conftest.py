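import numpy as np
import pytest

import synovnet as sn


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def archetype_cohort():
    """Default 44-patient planted-archetype cohort (4 clusters, 24+20)."""
    rng = np.random.default_rng(11)
    return sn.generate_archetype_cohort(sn.default_archetypes(), rng)


@pytest.fixture
def calibrated_cohort():
    """Default 108-patient cohort calibrated to the published summaries."""
    return sn.generate_cohort(sn.default_generator_config(seed=42))
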