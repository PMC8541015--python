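import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """Small in-memory phantom set shared by training-level tests."""
    from cascadeseg import PhantomSpec, generate_arrays
    mix = {"large": 0.3, "small": 0.3, "multiple": 0.3, "none": 0.1}
    images, masks, patterns = generate_arrays(
        20, mix, PhantomSpec(image_side=32), seed=99)
    return images, masks, patterns


def numeric_grad(f, x: np.ndarray, indices, h: float = 1e-2) -> np.ndarray:
    """Central-difference gradient of scalar f at selected flat indices."""
    out = np.zeros(len(indices))
    flat = x.reshape(-1)
    for j, idx in enumerate(indices):
        orig = flat[idx]
        flat[idx] = orig + h
        fp = f()
        flat[idx] = orig - h
        fm = f()
        flat[idx] = orig
        out[j] = (fp - fm) / (2 * h)
    return out
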