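import numpy as np
import pytest

from echoseg import phantom
from echoseg.network import MICRO_WIDTHS, ModelConfig


@pytest.fixture(scope="session")
def spec64():
    return phantom.scaled_spec(phantom.PhantomSpec(), 64)


@pytest.fixture(scope="session")
def spec32():
    return phantom.scaled_spec(phantom.PhantomSpec(), 32)


@pytest.fixture(scope="session")
def tiny_pair(spec64):
    """One 64×64 (image, labels) phantom pair."""
    return phantom.generate_phantom(spec64, seed=11)


@pytest.fixture(scope="session")
def micro_cfg():
    """Smallest model that still exercises every architectural piece."""
    return ModelConfig(encoder_widths=MICRO_WIDTHS, ppm_bins=(1, 2), decode_mode="DS")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def numgrad(f, x, eps=1e-3):
    """Central finite differences of a scalar function of array ``x``."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
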