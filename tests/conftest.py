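import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import entroprint as ep

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-condition cohort shared by unit tests."""
    cfg = ep.CohortConfig(
        n_subjects=30, n_rois=60, n_timepoints=400, seed=42
    )
    return ep.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    p1 = ep.entropy_profiles(small_cohort.timeseries, session=0)
    p2 = ep.entropy_profiles(small_cohort.timeseries, session=1)
    return p1, p2


@pytest.fixture(scope="session")
def midsize_cohort():
    """Default-condition cohort at the size used for screening/reliability
    checks (200 subjects, 100 ROIs, full-length runs)."""
    return ep.generate_cohort(ep.CohortConfig(n_subjects=200, n_rois=100,
                                              seed=20251))


@pytest.fixture(scope="session")
def midsize_profiles(midsize_cohort):
    p1 = ep.entropy_profiles(midsize_cohort.timeseries, session=0)
    p2 = ep.entropy_profiles(midsize_cohort.timeseries, session=1)
    return p1, p2


def rng_for(name: str) -> np.random.Generator:
    """Derandomised per-test generator."""
    return np.random.default_rng(abs(hash(name)) % (2**31))
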