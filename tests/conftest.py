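import numpy as np
import pytest

import connectokit as ck


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_design():
    """Two tiny groups, small enough for fast end-to-end runs."""
    return ck.CohortDesign(
        groups=[("TD", 3), ("ASD", 3)], n_voxels=60, k=3, t_raw=40, seed=11
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_design):
    return ck.simulate_cohort(tiny_design)


@pytest.fixture(scope="session")
def small_tc(rng):
    """Random positive network time courses, T=60 x K=5."""
    return np.abs(rng.normal(size=(60, 5))) + 0.1
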