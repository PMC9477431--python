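"""Magnitude + instantaneous-frequency spectral codec.

A 1016-sample segment is transformed by a centred STFT (Hann window 256,
hop 8) into a 2x128x128 tensor: a normalized log-magnitude channel and an
instantaneous-frequency (IF) channel. IF is the frame-to-frame difference of
the time-unwrapped phase, scaled by 1/pi so it lies in [-1, 1]; the absolute
phase of frame 0 is kept as an anchor so inversion is exact. The Nyquist
frequency row is dropped to realize the square 128x128 shape (DC is kept,
where drift and slow physiology live).

The codec is exactly invertible up to the dropped Nyquist row: magnitude is
de-normalized and exponentiated, IF is cumulatively summed onto the anchor
phase, and the complex STFT is inverted by windowed overlap-add.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

DEFAULT_WINDOW = 256
DEFAULT_HOP = 8
DEFAULT_RATE = 64.0
LOG_FLOOR = 1e-6

#: clinical frequency bands, half-open [low, high) Hz on bin centres;
#: the gaps between the printed band edges are folded into the lower band's
#: exclusive upper edge
BANDS = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 16.0),
    "beta": (16.0, 32.0),
}


@dataclass
class NormParams:
    """Affine map of log-magnitude into the network range [-1, 1]."""

    shift: float
    scale: float
    floor: float = LOG_FLOOR

    def normalize(self, logmag: np.ndarray) -> np.ndarray:
        return (logmag - self.shift) / self.scale

    def denormalize(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.shift


@dataclass
class SpectralTensor:
    """Two-channel time-frequency grid: normalized log-magnitude and IF."""

    mag: np.ndarray                # (F, T), normalized log-magnitude
    ifreq: np.ndarray              # (F, T), phase increments / pi
    norm: NormParams
    anchor_phase: np.ndarray       # (F,), absolute phase of frame 0 (radians)
    window: int = DEFAULT_WINDOW
    hop: int = DEFAULT_HOP
    rate: float = DEFAULT_RATE

    def __post_init__(self):
        if self.mag.shape != self.ifreq.shape:
            raise ValueError("mag and ifreq must share a shape")
        if not (np.isfinite(self.mag).all() and np.isfinite(self.ifreq).all()):
            raise ValueError("spectral grids must be finite")

    @property
    def array(self) -> np.ndarray:
        """(2, F, T) view: channel 0 magnitude, channel 1 IF."""
        return np.stack([self.mag, self.ifreq])


def _hann(window: int) -> np.ndarray:
    return _sig.windows.hann(window, sym=False)


def stft_complex(segment: np.ndarray, window: int = DEFAULT_WINDOW,
                 hop: int = DEFAULT_HOP) -> np.ndarray:
    """Centred STFT, all one-sided bins: (window//2 + 1, L//hop + 1) complex."""
    x = np.asarray(segment, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("segment must be 1-D")
    if not np.isfinite(x).all():
        raise ValueError("segment must be finite")
    if len(x) % hop != 0:
        raise ValueError(f"segment length {len(x)} not a multiple of hop {hop}")
    if len(x) < window:
        raise ValueError("segment shorter than the analysis window")
    pad = window // 2
    # odd reflection keeps the first derivative continuous at the segment
    # edges, which keeps boundary leakage into the (dropped) Nyquist row low
    xp = np.pad(x, (pad, pad), mode="reflect", reflect_type="odd")
    n_frames = len(x) // hop + 1
    w = _hann(window)
    frames = np.stack([xp[t * hop:t * hop + window] for t in range(n_frames)])
    return np.fft.rfft(frames * w, axis=1).T  # (F+1, T)


def instantaneous_frequency(phase: np.ndarray) -> np.ndarray:
    """Finite difference along time of the time-unwrapped phase (radians).

    Column 0 is zero by convention; the anchor (absolute first-frame phase)
    is carried separately by the caller.
    """
    phase = np.asarray(phase, dtype=np.float64)
    if phase.ndim != 2 or phase.shape[1] < 2:
        raise ValueError("phase must be (F, T) with at least two frames")
    unwrapped = np.unwrap(phase, axis=1)
    d = np.diff(unwrapped, axis=1)
    return np.concatenate([np.zeros((phase.shape[0], 1)), d], axis=1)


def fit_norm_params(segments, window: int = DEFAULT_WINDOW,
                    hop: int = DEFAULT_HOP, q: float = 0.0025) -> NormParams:
    """Dataset-level affine normalization fitted on log-magnitudes.

    Maps the [q, 1-q] quantile range of the pooled log-magnitude entries to
    [-1, 1]; with the default q, at least 99% of training entries land in
    the network range.
    """
    logs = []
    for seg in segments:
        z = stft_complex(seg, window, hop)[:-1]
        logs.append(np.log(np.abs(z) + LOG_FLOOR).ravel())
    pooled = np.concatenate(logs)
    lo, hi = np.quantile(pooled, [q, 1 - q])
    if hi - lo < 1e-12:
        return NormParams(shift=float(lo), scale=1.0)
    return NormParams(shift=float((hi + lo) / 2), scale=float((hi - lo) / 2))


def stft_features(segment: np.ndarray, window: int = DEFAULT_WINDOW,
                  hop: int = DEFAULT_HOP, rate: float = DEFAULT_RATE,
                  norm: NormParams | None = None) -> SpectralTensor:
    """Encode a segment as the two-channel magnitude + IF tensor.

    With the defaults a 1016-sample segment yields shape (2, 128, 128):
    128 frequency rows (Nyquist dropped) by 128 centred frames.
    """
    z = stft_complex(segment, window, hop)[:-1]  # drop Nyquist row
    mag = np.abs(z)
    phase = np.angle(z)
    logmag = np.log(mag + LOG_FLOOR)
    if norm is None:
        lo, hi = logmag.min(), logmag.max()
        if hi - lo < 1e-12:
            norm = NormParams(shift=float(lo), scale=1.0)
        else:
            norm = NormParams(shift=float((hi + lo) / 2), scale=float((hi - lo) / 2))
    ifreq = instantaneous_frequency(phase) / np.pi
    return SpectralTensor(
        mag=norm.normalize(logmag),
        ifreq=ifreq,
        norm=norm,
        anchor_phase=phase[:, 0].copy(),
        window=window,
        hop=hop,
        rate=rate,
    )


def invert_features(t: SpectralTensor) -> np.ndarray:
    """Inverse of :func:`stft_features`: overlap-add resynthesis.

    Output length is (T - 1) * hop, i.e. 1016 samples for the default
    geometry.
    """
    if t.norm is None:
        raise ValueError("norm_params required for inversion")
    logmag = t.norm.denormalize(t.mag)
    mag = np.maximum(np.exp(logmag) - t.norm.floor, 0.0)
    phase = t.anchor_phase[:, None] + np.cumsum(t.ifreq * np.pi, axis=1)
    phase[:, 0] = t.anchor_phase  # cumsum includes the zero first column
    z = mag * np.exp(1j * phase)
    z = np.concatenate([z, np.zeros((1, z.shape[1]))], axis=0)  # Nyquist row
    window, hop = t.window, t.hop
    n_frames = z.shape[1]
    length = (n_frames - 1) * hop
    w = _hann(window)
    frames = np.fft.irfft(z.T, n=window, axis=1)  # (T, window)
    total = length + window
    out = np.zeros(total)
    wsum = np.zeros(total)
    for i in range(n_frames):
        s = i * hop
        out[s:s + window] += frames[i] * w
        wsum[s:s + window] += w * w
    pad = window // 2
    sl = slice(pad, pad + length)
    y = out[sl] / np.maximum(wsum[sl], 1e-12)
    # project onto the representable band: the codec carries no content above
    # the highest retained bin centre, so anything beyond it is resynthesis
    # residue from the dropped Nyquist row
    n_rows = t.mag.shape[0]
    cutoff = (n_rows - 1) * t.rate / window
    spec = np.fft.rfft(y)
    freqs = np.fft.rfftfreq(length, 1.0 / t.rate)
    spec[freqs > cutoff + 1e-9] = 0.0
    return np.fft.irfft(spec, n=length)


def normalize(grid: np.ndarray, params: NormParams) -> np.ndarray:
    """Affine map into the network range; inverse of :func:`denormalize`."""
    grid = np.asarray(grid, dtype=np.float64)
    if not np.isfinite(grid).all():
        raise ValueError("grid must be finite")
    return params.normalize(grid)


def denormalize(grid: np.ndarray, params: NormParams) -> np.ndarray:
    return params.denormalize(np.asarray(grid, dtype=np.float64))


def band_rows(band: str, n_rows: int, rate: float = DEFAULT_RATE,
              n_fft: int = DEFAULT_WINDOW) -> np.ndarray:
    """Boolean mask of frequency rows whose bin centre lies in ``band``."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {list(BANDS)}")
    lo, hi = BANDS[band]
    centres = np.arange(n_rows) * rate / n_fft
    return (centres >= lo) & (centres < hi)
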