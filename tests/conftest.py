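import numpy as np
import pytest

from dcsanet import ModelConfig, SceneSpec, build_model, generate_dataset


@pytest.fixture(scope="session")
def tiny_model():
    return build_model(ModelConfig.tiny(), seed=0)


@pytest.fixture(scope="session")
def scene_samples():
    """Eight small synthetic scenes shared across tests."""
    samples, _ = generate_dataset(8, SceneSpec(size=64), seed=11)
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
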