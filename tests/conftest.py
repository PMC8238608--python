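import numpy as np
import pytest

from mammoseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noise_free_benign():
    """Benign disk phantom with no pixel noise (fibroglandular texture only)."""
    spec = PhantomSpec(tumor_class="benign", texture_sigma=0.0,
                       background_sigma=0.0, rng_seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_benign():
    return generate_phantom(PhantomSpec(tumor_class="benign", rng_seed=3))


@pytest.fixture(scope="session")
def default_malignant():
    return generate_phantom(PhantomSpec(tumor_class="malignant", rng_seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
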