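import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "package",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("package")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset():
    """Three populations with clearly distinct representative ancestries."""
    from helpers import make_dataset

    rows = [
        (0.7, 0.2, 0.1),
        (0.6, 0.3, 0.1),
        (0.1, 0.8, 0.1),
        (0.2, 0.7, 0.1),
        (0.1, 0.1, 0.8),
    ]
    labels = ["A", "A", "B", "B", "C"]
    return make_dataset(rows, labels)
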