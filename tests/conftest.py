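import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

from antagosim import (
    AssembledSystem,
    CommunitySpec,
    IntegrationSettings,
    assemble_system,
    integrate,
)

hyp_settings.register_profile(
    "ci", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_settings() -> IntegrationSettings:
    return IntegrationSettings()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session", autouse=True)
def warm_integrator():
    """Trigger numba compilation once so per-test timings are meaningful."""
    system = AssembledSystem(alpha=np.array([[1.0]]), r=np.array([1.0]), n_focal=1)
    integrate(system, np.array([0.1]), IntegrationSettings(t_end=1.0))


def random_system(seed: int, n_max: int = 5) -> AssembledSystem:
    """A small random community (possibly with antagonists) for oracle checks."""
    r = np.random.default_rng(seed)
    n = int(r.integers(1, n_max + 1))
    m = int(r.integers(0, 3)) if n + 2 <= n_max else 0
    spec = CommunitySpec(n=n, m=m, sigma=0.3, A=0.5, seed=seed)
    return assemble_system(spec)
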