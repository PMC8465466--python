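import numpy as np
import pytest

from facequant import cnn, faceregions, synthgen
from facequant.landmarks import template_landmarks


@pytest.fixture(scope="session")
def landmarks64():
    return template_landmarks(64)


@pytest.fixture(scope="session")
def partition64(landmarks64):
    return faceregions.partition_face(landmarks64)


@pytest.fixture(scope="session")
def masks64(partition64):
    return faceregions.region_masks(partition64, 64)


@pytest.fixture(scope="session")
def small_dataset():
    """Planted-effect dataset small enough for fast unit tests."""
    params = synthgen.SynthFaceParams(
        image_size=64, n_case=30, n_control=60, effect_amplitude=0.8, seed=42)
    return synthgen.generate_dataset(params)


@pytest.fixture(scope="session")
def trained_model(small_dataset):
    """A model trained for a handful of epochs on the small dataset."""
    train_set, test_set = synthgen.split_dataset(small_dataset, 0.7, seed=0)
    cfg = cnn.ExperimentConfig(
        backbone="small-resnet-like", learning_rate=0.1, batch_norm=True,
        input_size=64, epochs_max=8, seed=1)
    model = cnn.build_model(cfg)
    cnn.train(model, train_set, cfg)
    return model, train_set, test_set, cfg
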