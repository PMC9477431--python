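"""Filtering, resampling, and segmentation of raw recordings.

The pipeline order is fixed: high-pass and notch filtering at the original
sampling rate, then anti-aliased downsampling (default 64 Hz), then sliding-
window segmentation into 1016-sample windows with a stride of a quarter
window. Paired scalp/depth channels are segmented with identical start
indices so windows stay synchronized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

DEFAULT_WINDOW = 1016
DEFAULT_STRIDE = DEFAULT_WINDOW // 4  # 254
DEFAULT_RATE = 64.0

HIGHPASS_HZ = {"eeg": 1.0, "seeg": 0.5}
NOTCH_Q = 30.0


@dataclass
class Recording:
    """Multichannel recording: channels x samples, with names and geometry.

    ``coords`` maps channel name to a 3-vector of millimetre positions in a
    frame shared between scalp and depth electrodes.
    """

    data: np.ndarray
    rate: float
    channel_names: list[str]
    coords: dict[str, np.ndarray] | None = None
    exclude_channels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one name per channel required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


@dataclass
class SegmentSet:
    """Fixed-length windows cut from one channel."""

    segments: np.ndarray          # (n_segments, window)
    start_indices: np.ndarray     # sample offsets, constant stride
    channel: str
    rate: float

    def __post_init__(self):
        self.segments = np.asarray(self.segments, dtype=np.float64)
        self.start_indices = np.asarray(self.start_indices, dtype=np.int64)
        if self.segments.ndim != 2:
            raise ValueError("segments must be 2-D")
        if len(self.start_indices) != self.segments.shape[0]:
            raise ValueError("one start index per segment")
        if len(self.start_indices) > 1:
            strides = np.diff(self.start_indices)
            if not (strides > 0).all() or len(set(strides.tolist())) > 1:
                raise ValueError("start indices must increase with constant stride")

    def __len__(self) -> int:
        return self.segments.shape[0]


def filter_recording(rec: Recording, kind: str, line_hz: float = 50.0) -> Recording:
    """High-pass (1 Hz EEG / 0.5 Hz SEEG) + notch at line frequency harmonics.

    Zero-phase forward-backward filtering (4th-order Butterworth high-pass;
    IIR notch, Q=30) applied at the original sampling rate, before any
    resampling. Channels listed in ``exclude_channels`` are dropped.
    """
    if kind not in HIGHPASS_HZ:
        raise ValueError(f"unknown recording kind {kind!r}; expected 'eeg' or 'seeg'")
    keep = [i for i, name in enumerate(rec.channel_names)
            if name not in set(rec.exclude_channels)]
    if not keep:
        raise ValueError("all channels excluded")
    data = rec.data[keep].copy()
    names = [rec.channel_names[i] for i in keep]

    nyq = rec.rate / 2.0
    sos = signal.butter(4, HIGHPASS_HZ[kind], btype="highpass", fs=rec.rate,
                        output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)
    harmonic = line_hz
    while harmonic < nyq:
        b, a = signal.iirnotch(harmonic, Q=NOTCH_Q, fs=rec.rate)
        data = signal.filtfilt(b, a, data, axis=1)
        harmonic += line_hz
    return Recording(data, rec.rate, names, coords=rec.coords)


def resample_recording(rec: Recording, target_hz: float = DEFAULT_RATE) -> Recording:
    """Anti-aliased polyphase resampling to ``target_hz``."""
    if target_hz <= 0:
        raise ValueError("target rate must be positive")
    if target_hz > rec.rate:
        raise ValueError("target rate above source rate")
    if target_hz == rec.rate:
        return Recording(rec.data.copy(), rec.rate, list(rec.channel_names),
                         coords=rec.coords)
    frac = Fraction(target_hz / rec.rate).limit_denominator(10000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return Recording(data, target_hz, list(rec.channel_names), coords=rec.coords)


def segment_channel(rec: Recording, channel: str, win: int = DEFAULT_WINDOW,
                    stride: int | None = None) -> SegmentSet:
    """Sliding windows ``[i*stride, i*stride + win)`` over one channel."""
    if stride is None:
        stride = win // 4
    x = rec.channel(channel)
    if len(x) < win:
        raise ValueError(
            f"signal length {len(x)} shorter than window {win}"
        )
    n = (len(x) - win) // stride + 1
    starts = np.arange(n) * stride
    segs = np.stack([x[s:s + win] for s in starts])
    return SegmentSet(segs, starts, channel, rec.rate)


def segment_recording(rec: Recording, win: int = DEFAULT_WINDOW,
                      stride: int | None = None) -> dict[str, SegmentSet]:
    """Segment every channel with identical start indices."""
    return {name: segment_channel(rec, name, win=win, stride=stride)
            for name in rec.channel_names}


def preprocess_recording(rec: Recording, kind: str, line_hz: float = 50.0,
                         target_hz: float = DEFAULT_RATE) -> Recording:
    """Filter then resample, in that documented order."""
    return resample_recording(filter_recording(rec, kind, line_hz=line_hz),
                              target_hz)
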