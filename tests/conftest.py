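import numpy as np
import pytest

from longidiff.cohort import CohortSpec, apply_missingness, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Four subjects, five visits, 32^3 phantoms with the default atrophy."""
    return generate_cohort(CohortSpec(n_subjects=4, n_visits=5, seed=11))


@pytest.fixture(scope="session")
def small_cohort_pf(small_cohort):
    return apply_missingness(small_cohort, "PF")
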