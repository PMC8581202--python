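import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture, HealthCheck.too_slow],
)
settings.load_profile("default")

from mibci import FeatureMatrix, SynthConfig, TrialSet, generate_mi_trials


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trialset(rng, n_trials=6, n_channels=3, n_samples=64, fs=64.0, t0=0.0):
    """Random valid TrialSet for I/O and preprocessing tests."""
    labels = np.resize([1, -1], n_trials)
    return TrialSet(
        data=rng.standard_normal((n_trials, n_channels, n_samples)),
        fs=fs,
        labels=labels,
        channel_names=[f"ch{i}" for i in range(n_channels)],
        t0=t0,
    )


@pytest.fixture
def small_trials(rng):
    return make_trialset(rng)


@pytest.fixture
def erd_trials():
    """Strongly lateralized two-class trials, small enough for unit tests."""
    return generate_mi_trials(SynthConfig(n_per_class=30, erd_depth=0.8, seed=11))


@pytest.fixture
def blob_features(rng):
    """Well-separated Gaussian features with both classes."""
    n = 40
    X = rng.standard_normal((2 * n, 3))
    X[:n, 0] += 3.0
    X[n:, 0] -= 3.0
    y = np.concatenate([np.ones(n, int), -np.ones(n, int)])
    return FeatureMatrix(X=X, y=y)
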