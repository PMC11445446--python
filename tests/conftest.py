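import warnings

import numpy as np
import pytest

from crevo.equilibrium import compute_equilibrium
from crevo.sampling import Environment, Strain, make_environment, sample_pool

warnings.filterwarnings("ignore", message=".*no consumer.*")


@pytest.fixture(scope="session")
def env2():
    return Environment(R=2, K=np.array([0.5, 0.5]))


@pytest.fixture(scope="session")
def two_specialists(env2):
    s1 = Strain("a", 0.0, np.array([1.0, 0.0]))
    s2 = Strain("b", 0.0, np.array([0.0, 1.0]))
    return [s1, s2]


@pytest.fixture(scope="session")
def skewed_monoculture():
    """Parent r = (1/2, 1/2) alone under supply shares (3/4, 1/4)."""
    env = Environment(R=2, K=np.array([0.75, 0.25]))
    parent = Strain("p", 0.0, np.array([0.5, 0.5]))
    return parent, env, compute_equilibrium([parent], env)


@pytest.fixture(scope="session")
def medium_community():
    """A moderately sized assembled community (R=40, ~60% saturation)."""
    env = make_environment(40)
    pool = sample_pool(40, 10, 200, std_X=0.05, seed=123)
    return pool, env, compute_equilibrium(pool, env)


@pytest.fixture(scope="session")
def medium_community_cv():
    """Same scale with non-uniform resource supply (cv = 0.2)."""
    env = make_environment(40, mode="cv", cv=0.2)
    pool = sample_pool(40, 10, 200, std_X=0.05, seed=321)
    return pool, env, compute_equilibrium(pool, env)
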