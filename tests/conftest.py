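import numpy as np
import pytest

from nodulemap import gapnet, phantom


@pytest.fixture(scope="session")
def small_phantom_config() -> phantom.PhantomConfig:
    """64-px phantom with near-equal bulk echogenicity so the class signal
    lives in the localized cue."""
    return phantom.PhantomConfig(
        image_size=64,
        nodule_area_range=(260, 560),
        benign_echogenicity=0.53,
        malignant_echogenicity=0.50,
        cue_echogenicity=0.20,
        cue_area_fraction=0.18,
        speckle_scale=0.40,
        calcification_count_range=(1, 3),
        cue_localization="center",
    )


@pytest.fixture(scope="session")
def tiny_dataset(small_phantom_config):
    return phantom.generate_dataset(small_phantom_config, 20, 20, seed=7)


@pytest.fixture(scope="session")
def tiny_model_spec(small_phantom_config) -> gapnet.ModelSpec:
    return gapnet.ModelSpec(conv_channels=(8, 16, 32), input_size=64)


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_model_spec, tiny_dataset):
    model, _ = gapnet.train(
        tiny_model_spec,
        tiny_dataset,
        gapnet.TrainConfig(epochs=12, batch_size=10, seed=3),
    )
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
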