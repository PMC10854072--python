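import numpy as np
import pytest

from mducnn import ScheduleConfig, SyntheticConfig, generate
from mducnn.models import mdu_config, unet_config


@pytest.fixture(scope="session")
def tiny_mdu_cfg():
    """Width-reduced 2D multi-dimensional model for fast tests."""
    return mdu_config(2, depth=2,
                      schedule=ScheduleConfig(mode="formula", base_filters=(8, 16, 32)))


@pytest.fixture(scope="session")
def tiny_unet_cfg():
    return unet_config(2, depth=2, unet_widths=(8, 16, 32))


@pytest.fixture(scope="session")
def easy_samples_32():
    """Twelve small high-contrast samples for fast training tests."""
    cfg = SyntheticConfig.preset("fluorescence", size=(32, 32), n_images=12, seed=21)
    return generate(cfg).samples


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
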