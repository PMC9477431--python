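import numpy as np
import pandas as pd
import pytest

from e2sgan.preprocess import Recording


def bandlimited_segment(rng, n=1016, rate=64.0, lo=1.0, hi=31.0):
    """Random signal with Fourier support strictly inside [lo, hi] Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    spec = np.zeros(len(freqs), dtype=complex)
    m = (freqs >= lo) & (freqs <= hi)
    spec[m] = rng.standard_normal(m.sum()) + 1j * rng.standard_normal(m.sum())
    x = np.fft.irfft(spec, n=n)
    return x / (x.std() + 1e-12)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def segment_factory(rng):
    def make(n=1016, rate=64.0, lo=1.0, hi=31.0):
        return bandlimited_segment(rng, n, rate, lo, hi)
    return make


@pytest.fixture
def small_recording(rng):
    data = rng.standard_normal((3, 4096))
    return Recording(data, 64.0, ["A", "B", "C"])


def line_geometry(n_eeg=2, n_seeg=8):
    """Scalp channels at the ends of a line of depth contacts, coplanar, so
    scalp-to-contact distances step uniformly along the line."""
    rows = [("E01", 90.0, 0.0, 30.0), ("E02", -90.0, 0.0, 30.0)][:n_eeg]
    for j, x in enumerate(np.linspace(45.0, -45.0, n_seeg)):
        rows.append((f"S{j + 1:02d}", x, 0.0, 30.0))
    return pd.DataFrame(rows, columns=["channel", "x", "y", "z"])
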