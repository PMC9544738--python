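import numpy as np
import pytest

from connfinger import CohortParams, make_atlas, make_cohort


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale cohort: 3 subjects, short rest runs, one run of each kind."""
    return CohortParams(n_subjects=3, n_rest_volumes=60,
                        rest_runs_per_subject=1, task_runs_per_subject=1,
                        master_seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return make_cohort(small_params)


@pytest.fixture(scope="session")
def atlas():
    return make_atlas(CohortParams(n_subjects=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
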