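import numpy as np
import pytest

from soyfix import inference, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def fast_settings():
    """Small sampler settings for structural tests (not for inference
    quality assertions)."""
    return inference.McmcSettings(seed=7, chains=2, warmup=400, retained_total=400)


@pytest.fixture(scope="session")
def small_dataset():
    """Three-study synthetic dataset on the nine-stage schedule."""
    cfg = synthetic.GeneratorConfig(
        seed=11, n_studies=3, schedule=list(synthetic.NINE_STAGE_SCHEDULE)
    )
    return synthetic.generate_dataset(cfg)
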