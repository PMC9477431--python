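"""Synthetic paired scalp/depth recordings with controllable geometry.

Emulates the physical premise of scalp/intracranial recording: a set of
band-limited oscillatory sources inside the head, depth (SEEG-like) channels
dominated by their nearest source, and scalp (EEG-like) channels observing a
distance-attenuated, low-pass-smoothed summation of all sources plus sensor
noise. Spectral similarity between a scalp channel and a depth channel then
decays with their physical distance, and ``exception_links`` inject
"far but similar" pairs that break the monotone trend on purpose.

Sources are amplitude-modulated band-limited noise bursts with distinct
centre frequencies by default, so per-channel power spectra are
non-degenerate and spectral matching has signal to work with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import Recording

EEG_SHELL_MM = 95.0     # scalp hemisphere radius
SEEG_MAX_MM = 60.0      # depth electrodes confined inside this radius


@dataclass
class SourceModel:
    """Configuration of the latent source population.

    ``attenuation_exponent`` is the unitless decay power p of the coupling
    gain 1 / (1 + (d / reference_mm)^p). ``exception_links`` is a list of
    (eeg_channel, seeg_channel, gain) triples adding the named depth
    channel's dominant source directly to the scalp channel, overriding
    distance attenuation.
    """

    n_sources: int | None = None            # default: one source per depth channel
    source_positions: np.ndarray | None = None
    band_profiles: list[tuple[float, float]] | None = None  # (centre Hz, bandwidth Hz)
    burst_rate: float = 0.5                 # amplitude-burst events per second
    noise_sd: float = 0.3                   # channel noise, units of source SD
    attenuation_exponent: float = 2.0
    reference_mm: float = 10.0
    eeg_lowpass_hz: float = 12.0            # scalp smoothing (skull/scalp layers)
    exception_links: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_sources is not None and self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.attenuation_exponent <= 0:
            raise ValueError("attenuation_exponent must be > 0")
        for link in self.exception_links:
            if not np.isfinite(link[2]):
                raise ValueError("exception gains must be finite")


@dataclass
class PairedRecording:
    """Simultaneous scalp and depth recordings plus the injected ground truth."""

    eeg: Recording
    seeg: Recording
    truth_pairs: list[tuple[str, str]]

    def __post_init__(self):
        if self.eeg.n_samples != self.seeg.n_samples:
            raise ValueError("eeg and seeg must have identical sample counts")
        if self.eeg.rate != self.seeg.rate:
            raise ValueError("eeg and seeg must share the sampling rate")
        eeg_names = set(self.eeg.channel_names)
        seeg_names = set(self.seeg.channel_names)
        for e, s in self.truth_pairs:
            if e not in eeg_names or s not in seeg_names:
                raise ValueError(f"truth pair ({e}, {s}) references unknown channel")


def make_geometry(n_eeg: int, n_seeg: int, seed: int = 0):
    """Electrode coordinate table: scalp channels on a hemisphere shell,
    depth channels inside it. Returns a pandas DataFrame with columns
    channel, x, y, z (millimetres)."""
    import pandas as pd

    if n_eeg < 1 or n_seeg < 1:
        raise ValueError("channel counts must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_eeg):
        # uniform on the upper hemisphere shell
        v = rng.standard_normal(3)
        v[2] = abs(v[2]) + 0.1
        v = v / np.linalg.norm(v) * EEG_SHELL_MM
        rows.append((f"E{i + 1:02d}", *v))
    for j in range(n_seeg):
        r = SEEG_MAX_MM * rng.uniform(0.3, 1.0) ** (1 / 3)
        v = rng.standard_normal(3)
        v[2] = abs(v[2])
        v = v / np.linalg.norm(v) * r
        rows.append((f"S{j + 1:02d}", *v))
    return pd.DataFrame(rows, columns=["channel", "x", "y", "z"])


def _bandpass_noise(rng, n, rate, centre, bw):
    lo = max(centre - bw / 2, 0.2)
    hi = min(centre + bw / 2, rate / 2 - 0.2)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x


def _burst_envelope(rng, n, rate, rate_per_s):
    """Baseline plus raised-cosine bursts at Poisson event times."""
    env = np.full(n, 0.4)
    if rate_per_s <= 0:
        return np.ones(n)
    n_events = rng.poisson(rate_per_s * n / rate)
    width = int(round(rate))  # 1 s bumps
    bump = signal.windows.hann(width)
    for t in rng.integers(0, max(n - width, 1), size=n_events):
        env[t:t + width] += bump[: n - t]
    return env


def _gain(dist, p, d0):
    return 1.0 / (1.0 + (dist / d0) ** p)


def _lowpass_power_gain(freq_hz, cutoff, rate):
    """Squared magnitude response of the scalp smoothing filter (filtfilt)."""
    sos = signal.butter(2, cutoff, btype="lowpass", fs=rate, output="sos")
    _, h = signal.sosfreqz(sos, worN=[max(freq_hz, 1e-3)], fs=rate)
    return float(np.abs(h[0]) ** 2)


def make_paired_recording(model: SourceModel, n_eeg: int, n_seeg: int,
                          duration_s: float, rate_hz: float = 64.0,
                          geometry=None) -> PairedRecording:
    """Simulate simultaneous scalp/depth recordings under ``model``.

    Deterministic given ``model.seed``. ``geometry`` may be a coordinate
    table from :func:`make_geometry`; by default one is derived from the
    same seed.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate must be positive")
    if n_eeg < 1 or n_seeg < 1:
        raise ValueError("channel counts must be >= 1")
    n = int(round(duration_s * rate_hz))
    rng = np.random.default_rng(model.seed)

    if geometry is None:
        geometry = make_geometry(n_eeg, n_seeg, seed=model.seed)
    coords = {r.channel: np.array([r.x, r.y, r.z]) for r in geometry.itertuples()}
    eeg_names = [f"E{i + 1:02d}" for i in range(n_eeg)]
    seeg_names = [f"S{j + 1:02d}" for j in range(n_seeg)]
    eeg_pos = np.stack([coords[c] for c in eeg_names])
    seeg_pos = np.stack([coords[c] for c in seeg_names])

    if model.source_positions is not None:
        src_pos = np.asarray(model.source_positions, dtype=float)
    else:
        src_pos = seeg_pos.copy()  # anchor one source at each depth site
    k = src_pos.shape[0]
    if model.n_sources is not None and model.n_sources != k:
        raise ValueError("n_sources inconsistent with source_positions")

    if model.band_profiles is not None:
        bands = list(model.band_profiles)
        if len(bands) != k:
            raise ValueError("one band profile per source required")
    else:
        centres = np.linspace(3.0, min(27.0, rate_hz / 2 - 5), k)
        bands = [(float(c), 2.0) for c in centres]

    sources = np.zeros((k, n))
    for i, (centre, bw) in enumerate(bands):
        x = _bandpass_noise(rng, n, rate_hz, centre, bw)
        x = x * _burst_envelope(rng, n, rate_hz, model.burst_rate)
        sources[i] = x / (x.std() + 1e-12)

    p, d0 = model.attenuation_exponent, model.reference_mm
    a = _gain(np.linalg.norm(seeg_pos[:, None] - src_pos[None], axis=2), p, d0)
    b = _gain(np.linalg.norm(eeg_pos[:, None] - src_pos[None], axis=2), p, d0)

    # each channel's clean mixture is standardized to unit SD before noise is
    # added, so noise_sd is a per-channel noise fraction regardless of how
    # strongly distance attenuates the mixture (recording gain is arbitrary
    # anyway); per-channel rescaling leaves every correlation- and
    # PSD-shape-based property intact
    seeg_clean = a @ sources
    seeg_scale = seeg_clean.std(axis=1, keepdims=True) + 1e-12
    seeg_clean /= seeg_scale
    seeg_data = seeg_clean + model.noise_sd * rng.standard_normal((n_seeg, n))

    eeg_mix = b @ sources
    sos_lp = signal.butter(2, model.eeg_lowpass_hz, btype="lowpass", fs=rate_hz,
                           output="sos")
    eeg_sm = signal.sosfiltfilt(sos_lp, eeg_mix, axis=1)

    # effective coupling weights for ground truth: attenuation x smoothing gain
    gamma = np.array([_lowpass_power_gain(c, model.eeg_lowpass_hz, rate_hz)
                      for c, _ in bands])
    w_eff = (b * gamma[None]) @ a.T / seeg_scale.T  # (n_eeg, n_seeg)

    for eeg_ch, seeg_ch, gain in model.exception_links:
        i = eeg_names.index(eeg_ch)
        j = seeg_names.index(seeg_ch)
        dom = int(np.argmax(a[j]))  # the depth channel's dominant source
        eeg_sm[i] += gain * eeg_sm[i].std() * sources[dom]
        w_eff[i, j] += abs(gain) * w_eff[i].max()

    eeg_scale = eeg_sm.std(axis=1, keepdims=True) + 1e-12
    eeg_data = eeg_sm / eeg_scale \
        + model.noise_sd * rng.standard_normal((n_eeg, n))

    truth_pairs = [(eeg_names[i], seeg_names[int(np.argmax(w_eff[i]))])
                   for i in range(n_eeg)]

    eeg_coords = {c: coords[c] for c in eeg_names}
    seeg_coords = {c: coords[c] for c in seeg_names}
    return PairedRecording(
        eeg=Recording(eeg_data, rate_hz, eeg_names, coords=eeg_coords),
        seeg=Recording(seeg_data, rate_hz, seeg_names, coords=seeg_coords),
        truth_pairs=truth_pairs,
    )
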