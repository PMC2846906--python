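import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from momentpls.io import RefinedMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_refined(values: np.ndarray, labels=None) -> RefinedMatrix:
    """Wrap a plain array as a RefinedMatrix with synthetic ids/labels."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    if labels is None:
        labels = np.array([1 if j < n // 2 else -1 for j in range(n)])
        if len(set(labels)) < 2:
            labels[0] = -labels[0]
    return RefinedMatrix(
        mz_axis=np.arange(1.0, m + 1.0),
        intensities=values,
        sample_ids=[f"s{j}" for j in range(n)],
        labels=np.asarray(labels),
    )


@pytest.fixture
def small_matrix(rng):
    return make_refined(rng.normal(10.0, 2.0, size=(120, 12)))
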