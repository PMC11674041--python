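import numpy as np
import pytest

from hepaseg import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small metastatic phantom with all confounders, shared read-only."""
    cfg = PhantomConfig(shape=(12, 48, 48), lesion_count=2,
                        lesion_radius_range=(2.0, 4.0), seed=3)
    return cfg, generate_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
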