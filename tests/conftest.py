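import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260142)


@pytest.fixture
def paired_records():
    """Small balanced k=2 dataset as (subject, occasion, value) records."""
    rng = np.random.default_rng(7)
    true = 5.0 + 2.0 * rng.standard_normal(10)
    records = []
    for i, t in enumerate(true, start=1):
        for j in range(1, 3):
            records.append((i, j, t + rng.standard_normal()))
    return records
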