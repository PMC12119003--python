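import numpy as np
import pytest

from lesiondet.data_synth import SceneSpec, build_dataset
from lesiondet.model_zoo import ModelVariant, build_model
from lesiondet.train import TrainConfig, evaluate, train


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small, fully seeded 5-class synthetic dataset (64 px scenes)."""
    root = tmp_path_factory.mktemp("synthdata")
    spec = SceneSpec(image_hw=(64, 64), area_range=(40.0, 400.0),
                     num_classes=5, mean_objects=2.0)
    manifest = build_dataset(root, 10, spec, seed=7, ratios=(0.7, 0.2, 0.1))
    return manifest


@pytest.fixture(scope="session")
def smoke_dataset(tmp_path_factory):
    """Eight training scenes for the seeded overfit smoke run."""
    root = tmp_path_factory.mktemp("smokedata")
    spec = SceneSpec(image_hw=(64, 64), area_range=(40.0, 400.0),
                     num_classes=5, mean_objects=2.0)
    return build_dataset(root, 8, spec, seed=7, ratios=(1.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def smoke_run(smoke_dataset):
    """One seeded desk-scale overfit: 8 images, 64 px, 120 iterations.

    Returns (trained model, history, train-split mAP50 trained/untrained).
    Session-scoped because the run takes a few minutes; several tests read
    different facets of the same run.
    """
    variant = ModelVariant(num_classes=5)
    cfg = TrainConfig(epochs=120, batch_size=8, lr=0.02, image_size=64,
                      seed=0, max_iterations=120)
    model, history = train(variant, smoke_dataset, cfg)
    trained = evaluate(model, smoke_dataset, "train", image_size=64)
    untrained = evaluate(build_model(variant), smoke_dataset, "train", image_size=64)
    return model, history, trained, untrained
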