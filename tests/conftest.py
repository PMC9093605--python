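import numpy as np
import pytest

from sproutquant import PipelineConfig, SyntheticSpec, generate


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    """Default pipeline configuration (also the validated one)."""
    return PipelineConfig()


@pytest.fixture(scope="session")
def spheroid_image(cfg):
    """One seeded synthetic spheroid (5 attached sprouts) plus ground truth."""
    img, truth = generate(SyntheticSpec(n_attached=5, seed=42))
    return img, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
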