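import numpy as np
import pytest

from ventmorph import CohortConfig, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort for fast structural tests."""
    cfg = CohortConfig(n_inph=8, n_control=6, mesh_resolution=2,
                       cortex_resolution=2, seed=123)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size study cohort (33 INPH + 23 controls) used by the
    planted-ground-truth recovery tests."""
    return generate_cohort(CohortConfig(seed=7, cortex_resolution=3))
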