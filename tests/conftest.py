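import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_example():
    """Two unit squares offset by (2, 2): T2 = 48, F = 20, df = (2, 5)."""
    a = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
    b = a + 2.0
    return a, b


@pytest.fixture(scope="session")
def small_dataset():
    """A 2-embryo, 2-section synthetic dataset with truth retained."""
    from cordmapper import preset_truth, simulate_dataset

    truth = preset_truth("dI2_default")
    return simulate_dataset(truth, n_embryos=2, sections_per_level=2, seed=11)
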