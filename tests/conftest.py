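import numpy as np
import pytest

import stepconn as sc


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_cohort():
    """One mid-size cohort with a planted degree-WHR association."""
    config = sc.SimulationConfig(
        n_subjects=120, n_regions=60, n_timepoints=400,
        planted_effect_r=0.35, n_true_seeds=26, rng_seed=424242,
    )
    return sc.generate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted effects of any kind."""
    config = sc.SimulationConfig(
        n_subjects=60, n_regions=40, n_timepoints=200, rng_seed=99,
    )
    return sc.generate_cohort(config)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort for I/O and pipeline plumbing tests."""
    config = sc.SimulationConfig(
        n_subjects=40, n_regions=30, n_timepoints=400,
        planted_effect_r=0.5, n_true_seeds=26, rng_seed=7,
    )
    return sc.generate_cohort(config)
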