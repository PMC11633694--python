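import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import omtrial as ot
from omtrial.synthetic import sample_item_locations, sample_response

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def screen() -> ot.ScreenGeometry:
    return ot.ScreenGeometry()


@pytest.fixture(scope="session")
def cohort() -> ot.CohortData:
    """Default study-sized null cohort (8 subjects, 5:3, 640 trials)."""
    return ot.generate_cohort(ot.CohortConfig(seed=7))


def make_two_item_data(seed, n, params, screen, min_sep=150.0):
    """Simulate n two-item trials from a known mixture; returns (X, T, N)."""
    rng = np.random.default_rng(seed)
    X, T, N = [], [], []
    for _ in range(n):
        pts = sample_item_locations(2, screen, min_sep, rng)
        _, resp, _ = sample_response(params, pts[0], pts[1:], screen, rng)
        X.append(resp)
        T.append(pts[0])
        N.append(pts[1])
    return np.asarray(X), np.asarray(T), np.asarray(N)


@pytest.fixture(scope="session")
def two_item_data(screen):
    return make_two_item_data
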