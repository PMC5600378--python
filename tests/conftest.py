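import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from navskill import world

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def perfect_agent():
    """All skills at ceiling: every noise scale collapses to zero."""
    return world.AgentParams(
        motor_skill=1.0,
        memory_fidelity=1.0,
        map_skill=1.0,
        nav_skill=1.0,
        aim_precision=1.0,
    )


@pytest.fixture
def average_agent():
    return world.AgentParams(0.5, 0.5, 0.5, 0.5, 0.5)


@pytest.fixture(scope="session")
def planted_loadings():
    """Well-separated 3-factor structure over 8 tasks (communalities ~0.5)."""
    L = np.zeros((8, 3))
    L[[0, 1, 2], 0] = [0.75, 0.70, 0.65]
    L[[3, 4, 5], 1] = [0.75, 0.70, 0.65]
    L[[6, 7], 2] = [0.72, 0.68]
    # anchor the two-indicator factor with one cross-loading so the ML
    # solution is well identified (a bare doublet famously drifts into
    # boundary/Heywood optima even at large n)
    L[5, 2] = 0.35
    return L


@pytest.fixture(scope="session")
def small_study():
    """One simulated 30-agent study reused across read-only tests."""
    from navskill import pipeline

    z, nav = pipeline.simulate_and_score(n_agents=30, seed=77)
    return z, nav
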