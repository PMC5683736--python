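import numpy as np
import pytest

from iecvstage import CohortConfig, compute_cohort_metrics, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=123)


@pytest.fixture(scope="session")
def cohort(default_config):
    """Default-size study cohort (37 controls + 166 AS)."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for law-of-large-numbers checks."""
    return generate_cohort(CohortConfig(n_controls=2000, n_as=4000, seed=77))


@pytest.fixture(scope="session")
def big_metrics(big_cohort):
    return compute_cohort_metrics(big_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
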