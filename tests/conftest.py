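import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pulsegrip.network import ModelConfig, build_model
from pulsegrip.preprocess import PreprocessConfig, preprocess_dataset, split_dataset
from pulsegrip.synthetic import generate_dataset

# Tiny study: 15 s trials at 20 Hz -> 300 samples -> three 100-sample windows.
TINY_FS = 20.0
TINY_MODEL = ModelConfig(
    input_length=100,
    n_classes=2,
    cnn_stem_channels=8,
    bottleneck_channels=(4, 4, 8),
    lstm_hidden_1=8,
    lstm_out=4,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small two-class porcine artery/vein dataset, split and conditioned."""
    ds = generate_dataset("porcine_I", 10, TINY_FS, seed=3)
    ds = split_dataset(ds, (6, 2, 2), seed=3)
    return preprocess_dataset(ds, PreprocessConfig())


@pytest.fixture()
def tiny_model():
    return build_model(TINY_MODEL, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
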