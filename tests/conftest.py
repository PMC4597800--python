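import numpy as np
import pytest

import crabias as cb


@pytest.fixture(scope="session")
def preset():
    return cb.flightcrew_preset()


@pytest.fixture(scope="session")
def preset_cohort(preset):
    """One fixed preset cohort shared across tests (seed 1)."""
    return cb.generate_cohort(preset, 1)


@pytest.fixture(scope="session")
def preset_joint(preset):
    return cb.build_discrete_joint(preset, age_grid=17)


@pytest.fixture(scope="session")
def big_cohort(preset):
    """A large cohort for Monte Carlo error checks (n = 10^6, seed 7)."""
    import dataclasses

    cfg = dataclasses.replace(preset, n=1_000_000)
    return cb.generate_cohort(cfg, 7)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)
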