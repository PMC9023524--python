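import numpy as np
import pytest

from dyadkit.simulate import ScanSimConfig, TTSimConfig, make_linescan, make_ttubule_image


@pytest.fixture(scope="session")
def striated_image():
    """Default-condition striated T-tubule image with ground truth (seed 1)."""
    return make_ttubule_image(TTSimConfig(), 1)


@pytest.fixture(scope="session")
def mixed_image():
    """Image with dropout and longitudinal elements (seed 7)."""
    cfg = TTSimConfig(transverse_dropout=0.3, longitudinal_density=0.15)
    return cfg, *make_ttubule_image(cfg, 7)


@pytest.fixture(scope="session")
def paced_scan():
    """Fully coupled paced line scan (seed 1)."""
    cfg = ScanSimConfig(duration_s=6.0)
    return cfg, *make_linescan(cfg, 1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
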