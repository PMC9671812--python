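import numpy as np
import pytest

from metastate.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def big_cohort():
    """Default 8-endpoint cohort at n=20,000 — shared across read-only tests."""
    cfg = CohortConfig(n_participants=20000, seed=7)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_participants=2500, n_centers=5, seed=3,
                       missingness_fraction=0.0)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
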