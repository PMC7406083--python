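import numpy as np
import pytest

from depthseg import (GenConfig, ModelSpec, build_model, build_stimulus_set,
                      make_training_datasets, train)


@pytest.fixture(scope="session")
def tiny_gen() -> GenConfig:
    """Small, fast generator configuration shared across tests."""
    return GenConfig(K=3, E=6, B=2, image_size=16, seed=7)


@pytest.fixture(scope="session")
def tiny_set(tiny_gen):
    return build_stimulus_set(tiny_gen.K, tiny_gen.E, tiny_gen.B, tiny_gen)


@pytest.fixture(scope="session")
def tiny_spec(tiny_gen) -> ModelSpec:
    return ModelSpec(n_blocks=1, residual=False, base_channels=8,
                     n_classes=tiny_gen.K, input_size=tiny_gen.image_size)


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_gen, tiny_spec):
    """A briefly trained small classifier on the segmented diet; used by
    evaluation and attribution tests that need a non-degenerate model."""
    seg, _ = make_training_datasets(tiny_gen.K, 12, tiny_gen, seed=99)
    model = build_model(tiny_spec, seed=0)
    train(model, seg.train, seg.val, epochs=4, seed=0, diet="segmented")
    return model


class StubModel:
    """Duck-typed classifier with a fixed scoring rule, for formula tests."""

    def __init__(self, n_classes: int, score_fn):
        from types import SimpleNamespace
        self.spec = SimpleNamespace(n_classes=n_classes)
        self._fn = score_fn

    def class_scores_batch(self, images):
        return np.stack([self._fn(np.asarray(img, dtype=float)) for img in images])

    def class_scores(self, image):
        return self.class_scores_batch(image[None])[0]


@pytest.fixture
def stub_model_factory():
    return StubModel
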