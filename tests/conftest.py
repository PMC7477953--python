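import numpy as np
import pytest

import laminarpac as lp


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def sham_cohort():
    """Small sham cohort with units, shared across read-only tests."""
    spec = lp.CohortSpec(n_animals=2, duration_s=120.0, fs=1000.0, seed=7,
                         n_pyr=8, n_int=6, n_ms_gaba=8, n_ms_chol=4)
    return lp.make_cohort(spec, lp.sham_effects())


@pytest.fixture(scope="session")
def sham_aligned(sham_cohort):
    return lp.align_to_pyramidale(sham_cohort.recordings)
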