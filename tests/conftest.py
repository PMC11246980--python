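import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_dataset():
    """Teacher dataset with three well-separated class centroids in 24-d.

    Noise SD is far below the centroid separation, so a nearest-centroid
    rule (the independence oracle) is near-perfect on the same data.
    """
    from myocomp.intention import TeacherDataset

    gen = np.random.default_rng(7)
    centroids = {
        "rest": np.zeros(24),
        "grip": np.r_[np.full(12, 10.0), np.zeros(12)],
        "open": np.r_[np.zeros(12), np.full(12, 10.0)],
    }
    X, y = [], []
    for lab, c in centroids.items():
        X.append(c + gen.normal(0, 0.5, size=(60, 24)))
        y.extend([lab] * 60)
    return TeacherDataset(
        X=np.vstack(X), y=np.array(y), label_set=("rest", "grip", "open")
    ), centroids


@pytest.fixture(scope="session")
def control_summary():
    """One closed-loop control simulation shared across tests."""
    from myocomp.pipeline import RunConfig, run_control_sim

    return run_control_sim(RunConfig(seed=7))
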