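import numpy as np
import pytest

from netfailq.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort shared across read-only tests."""
    cfg = CohortConfig(n_normative=120, n_dad=6, n_ad=5, n_controls=3, seed=123)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
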