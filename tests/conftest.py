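import numpy as np
import pytest

from octrack import (
    PhantomSpec,
    UNetConfig,
    TrainConfig,
    build_model,
    make_dataset,
    train,
)


@pytest.fixture
def spec():
    return PhantomSpec()


@pytest.fixture
def clean_spec():
    """Noise-free limit: no speckle, no detector noise, no blur, no
    attenuation — intensity is exactly piecewise constant."""
    return PhantomSpec(
        speckle=False, detector_noise_sd=0.0, psf_sigma_px=0.0, attenuation_per_um=0.0
    )


@pytest.fixture(scope="session")
def toy_trained():
    """A small model trained briefly on a reduced phantom dataset; shared by
    every test that needs a plausible (not peak-quality) trained segmenter."""
    spec = PhantomSpec()
    train_ds, test_ds, _ = make_dataset(
        spec, n_eyes=4, n_per_eye=20, n_train_eyes=3, n_extra_augment=3, seed=11
    )
    model = build_model(UNetConfig(), seed=11)
    train(model, train_ds, TrainConfig(max_epochs=8, seed=11))
    return model, train_ds, test_ds, spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
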