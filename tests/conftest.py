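import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_distmat():
    """Factory for random valid distance matrices with string labels."""
    from phylocongruence import DistanceMatrix

    def make(n, seed=0, scale=1.0):
        r = np.random.default_rng(seed)
        X = r.uniform(0.05, scale, size=(n, n))
        X = (X + X.T) / 2.0
        np.fill_diagonal(X, 0.0)
        labels = tuple(f"s{i:02d}" for i in range(n))
        return DistanceMatrix(labels, X)

    return make
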