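import numpy as np
import pytest

from mario import SynthConfig, generate_pair, normalize_features


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_pair():
    """A small, well-separated paired fixture with ground truth."""
    cfg = SynthConfig(
        n_populations=3,
        n_cells_x=60,
        n_cells_y=120,
        p_shared=8,
        p_distinct_x=6,
        p_distinct_y=6,
        latent_dim=4,
        separation=3.0,
        noise_sd=0.3,
        seed=7,
    )
    x, y, truth = generate_pair(cfg)
    return normalize_features(x), normalize_features(y), truth
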