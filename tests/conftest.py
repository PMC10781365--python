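import numpy as np
import pytest

from discsal.fixtures import GeneratorConfig, generate_dataset, train_toy_model
from discsal.nn import Hyperparams, ModelAdapter, ToyCNN


@pytest.fixture(scope="session")
def small_dataset():
    """20 noisy separable images (10 per class) with annotations and manifest."""
    config = GeneratorConfig(seed=7)
    return generate_dataset(config, 10)


@pytest.fixture(scope="session")
def trained_model(small_dataset):
    """Toy classifier trained on a 100-image separable set (shared, read-only)."""
    samples, _, _ = generate_dataset(GeneratorConfig(seed=13), 50)
    return train_toy_model(samples, [s.label for s in samples], seed=3)


def make_linear_adapter(image_size=8, seed=0, channels=(3,)):
    """A ReLU-free 1x1-conv net: an exactly linear model under the adapter contract."""
    hp = Hyperparams(channels=channels, kernel=1, stride=1, use_relu=False)
    net = ToyCNN(image_size, 2, hp, seed=seed)
    return ModelAdapter(net, model_id="linear")


def make_tiny_adapter(image_size=8, seed=0, channels=(4, 8)):
    """A small ReLU conv net for oracle comparisons."""
    hp = Hyperparams(channels=channels, kernel=3, stride=2)
    net = ToyCNN(image_size, 2, hp, seed=seed)
    return ModelAdapter(net, model_id="tiny")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
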