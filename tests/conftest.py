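import numpy as np
import pytest

import retinaug as ra


@pytest.fixture(scope="session")
def clean_phantom() -> ra.PhantomSample:
    """Noise-free phantom with all structure types present."""
    return ra.generate_phantom(ra.PhantomSpec(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_phantom() -> ra.PhantomSample:
    return ra.generate_phantom(ra.PhantomSpec(seed=12, noise_sd=0.01))


@pytest.fixture(scope="session")
def small_pool() -> ra.IlluminantPool:
    """Pool from 5 synthetic references × 3 estimators = 15 rows."""
    refs = ra.generate_reference_set(5, seed=42)
    return ra.build_pool([(im, fov) for im, fov, _ in refs])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
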