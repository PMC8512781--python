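import numpy as np
import pytest

from vowelbci.images import build_image_set
from vowelbci.synthetic import SyntheticConfig, dataset_trialsets


@pytest.fixture(scope="session")
def small_imageset():
    """One subject, 8-channel montage, ~100 images/class, moderate SNR."""
    cfg = SyntheticConfig(n_subjects=1, n_trials_per_vowel=2, n_channels=8, snr=5, seed=11)
    ts = dataset_trialsets(cfg, subjects=[0])[0]
    return build_image_set(ts)


@pytest.fixture(scope="session")
def small_images_xy(small_imageset):
    X, y, _ = small_imageset.stack()
    return X, y


@pytest.fixture
def rng():
    return np.random.default_rng(0)
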