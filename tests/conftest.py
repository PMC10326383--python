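import numpy as np
import pytest
from hypothesis import settings

from bnloopgan.augmentation import scale_sample
from bnloopgan.gan_core import TrainingConfig, pretrain_gan
from bnloopgan.synthetic_data import SyntheticSpec, generate_connectomes

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def desk_dataset():
    """Strong-effect two-class dataset at the reduced 40-region geometry."""
    spec = SyntheticSpec(n_regions=40, n_per_class=20, n_modalities=2,
                         effect_edges=0.1, effect_size=2.0, noise_sd=0.5,
                         seed=11)
    return [scale_sample(s) for s in generate_connectomes(spec)]


@pytest.fixture(scope="session")
def desk_gan(desk_dataset):
    """A briefly pre-trained conditional GAN at reduced width."""
    cfg = TrainingConfig(n_modalities=2, image_size=40, width=0.25,
                         epochs=2, batch_size=16, n_critic=2, seed=0)
    return pretrain_gan(desk_dataset, cfg)
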