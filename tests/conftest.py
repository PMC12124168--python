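import warnings

import numpy as np
import pytest

from rrtsurvey.design import (
    Stratum,
    StudyDesign,
    default_study_design,
    default_true_params,
)


@pytest.fixture(scope="session")
def default_design():
    return default_study_design()


@pytest.fixture(scope="session")
def default_params(default_design):
    return default_true_params(default_design)


@pytest.fixture(scope="session")
def tiny_design():
    """Six-stratum design scaled down for fast end-to-end tests."""
    strata = (
        Stratum("manaus", "rural", 12),
        Stratum("manaus", "peri_urban", 9),
        Stratum("manaus", "urban", 30),
        Stratum("carauari", "rural", 7),
        Stratum("carauari", "peri_urban", 4),
        Stratum("carauari", "urban", 16),
    )
    return StudyDesign(strata=strata)


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


def simulate_masked_binary(n, pi_s, pi_ns, p_s, rng):
    """Independent data generator for masked binary responses (oracle side)."""
    z = rng.random(n) < p_s
    return np.where(z, rng.random(n) < pi_s, rng.random(n) < pi_ns).astype(int)


@pytest.fixture(autouse=True)
def _fail_on_unraisable():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield
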