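import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """48-image dataset (2 specimens x 6 times x 2 lightings x 2 angles)."""
    from freshfusion.synthetic import DatasetConfig, generate_dataset

    cfg = DatasetConfig(n_specimens=2, lightings=("natural_D65", "warm_LED"),
                        angles_deg=(0, 60), shots_per_condition=1,
                        image_size=32)
    return generate_dataset(cfg, seed=7)


def finite_difference(fn, x, eps=1e-6):
    """Central-difference gradient of a scalar function of array ``x``."""
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = fn()
        x[i] = orig - eps
        fm = fn()
        x[i] = orig
        grad[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad
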