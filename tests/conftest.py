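import numpy as np
import pytest

from plqct.config import RunConfig
from plqct.synthetic_data import PhantomSpec, generate_phantom_volume


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom (truth 130 mg/cc) with its manifest."""
    spec = PhantomSpec(true_trabecular_density=130.0, noise_sd_hu=0.0, seed=1)
    vol, manifest = generate_phantom_volume(spec)
    return vol, manifest, spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
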