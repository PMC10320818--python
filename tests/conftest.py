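import numpy as np
import pytest

from bmsampler.fitting import parameter_recovery
from bmsampler.networks import Query, default_joint, enumerate_queries


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def cc_joint():
    return default_joint("common_cause")


@pytest.fixture(scope="session")
def chain_joint():
    return default_joint("chain")


@pytest.fixture(scope="session")
def ce_joint():
    return default_joint("common_effect")


@pytest.fixture(scope="session")
def queries():
    return enumerate_queries()


@pytest.fixture(scope="session")
def conflict_query():
    """The focal conflict inference P(X1=1 | Y=1, X2=0)."""
    return Query("X1", 1, (("Y", 1), ("X2", 0)))


@pytest.fixture(scope="session")
def recovery_run():
    """One shared generate-and-refit recovery study (30 participants,
    coarse grid, 2,000 simulations per cell); reused by the recovery
    acceptance check and the identifiability property test."""
    return parameter_recovery(n_participants=30, n_sims=2000, random_state=7)
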