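import numpy as np
import pytest

from eegclean.model import Montage, Recording
from eegclean.montages import standard_cap_32


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cap32():
    return standard_cap_32()


def make_field_recording(
    montage: Montage,
    n_samples: int = 4000,
    fs: float = 200.0,
    seed: int = 0,
    n_sources: int = 30,
    sigma: float = 0.5,
    signal_sd: float = 20.0,
    noise_sd: float = 1.0,
) -> Recording:
    """Small, spatially smooth, correlated multichannel recording.

    Shared helper for detection/reference tests: spline-predictable by
    construction, no drift, no line noise.
    """
    rng = np.random.default_rng(seed)
    montage = montage.normalized()
    dirs = rng.standard_normal((n_sources, 3))
    dirs[:, 2] = np.abs(dirs[:, 2]) * 0.8 + 0.2
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    src_pos = 0.8 * dirs
    d2 = ((montage.positions[:, None, :] - src_pos[None, :, :]) ** 2).sum(axis=2)
    gains = np.exp(-d2 / (2 * sigma**2))
    sources = rng.standard_normal((n_sources, n_samples))
    # mild temporal smoothing keeps window correlations realistic
    kernel = np.hanning(9)
    kernel /= kernel.sum()
    sources = np.apply_along_axis(lambda x: np.convolve(x, kernel, "same"), 1, sources)
    data = gains @ sources
    data /= data.std(axis=1, keepdims=True)
    data *= signal_sd * (1 + 0.05 * rng.standard_normal((len(montage), 1)))
    # per-channel noise jitter keeps the HF-ratio spread above sampling error
    floor = noise_sd * (1 + 0.1 * rng.standard_normal((len(montage), 1)))
    data += floor * rng.standard_normal(data.shape)
    return Recording(data, fs, montage)


@pytest.fixture
def field_recording(cap32):
    return make_field_recording(cap32, n_samples=6000, seed=3)
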