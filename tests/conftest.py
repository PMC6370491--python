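import numpy as np
import pytest

import dfcbench as d


@pytest.fixture(scope="session")
def atlas60():
    return d.generate_atlas(n_nodes=60, n_subnetworks=6, n_epochs=3, seed=5)


@pytest.fixture(scope="session")
def model_default():
    return d.ArtifactModel()


@pytest.fixture(scope="session")
def cohort_small(atlas60, model_default):
    """12 contaminated subjects, 60 nodes, 120 frames."""
    return d.generate_cohort(12, atlas=atlas60, model=model_default, seed=9)


@pytest.fixture(scope="session")
def subject(cohort_small):
    return cohort_small[0]


@pytest.fixture(scope="session")
def stack_small(subject):
    res = d.apply_pipeline(subject, "RAW")
    return d.window_connectivity(res, d.make_windows(120))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
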