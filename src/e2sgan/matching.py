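"""Scalp-to-depth channel matching.

The strategy pairs every depth (SEEG) channel with a scalp (EEG) channel as
candidates, sorts candidates by Euclidean distance, bins them into distance
intervals, and regresses spectral dissimilarity (Hellinger distance between
sum-normalized Welch power spectral densities) on distance within each bin.
A positive slope means similarity decays with distance inside that bin. The
proportion of positive slopes is accumulated over all segments; the interval
itv* = [a, b] with the highest proportion is selected, and each scalp
channel is paired with the unused depth channel whose distance is closest
to the interval's lower edge a.

A greedy nearest-neighbour variant (ignore similarity, repeatedly take the
globally smallest unassigned distance) is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as _sig

WELCH_NPERSEG = 256
DEFAULT_BIN_MM = 5.0


@dataclass
class CandidatePair:
    eeg_channel: str
    seeg_channel: str
    distance_mm: float
    similarity: float  # Hellinger distance in [0, 1], averaged over segments


@dataclass
class IntervalStats:
    low: float
    high: float
    n_pairs: int           # candidate pairs falling in the interval
    n_slopes: int          # regressions evaluated (one per channel x segment)
    positive_fraction: float
    mean_slope: float

    @property
    def positive(self) -> bool:
        return self.mean_slope > 0


@dataclass
class MatchResult:
    itv_star: tuple[float, float]
    per_interval: list[IntervalStats]
    pairs: list[tuple[str, str]]
    candidates: list[CandidatePair]

    @property
    def a(self) -> float:
        """Lower edge of the selected interval."""
        return self.itv_star[0]


def welch_psd(segment: np.ndarray, rate: float,
              nperseg: int = WELCH_NPERSEG) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with 50% overlap; nperseg capped at the segment length."""
    segment = np.asarray(segment, dtype=np.float64)
    nper = min(nperseg, len(segment))
    freqs, psd = _sig.welch(segment, fs=rate, nperseg=nper, noverlap=nper // 2)
    return freqs, psd


def hellinger_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Hellinger distance sqrt(1 - sum(sqrt(p * q))) on normalized vectors.

    Inputs are non-negative densities over the same support; they are
    normalized to sum to one internally. Symmetric, bounded in [0, 1],
    zero iff the normalized inputs coincide.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("densities must be non-negative")
    ps, qs = p.sum(), q.sum()
    if ps <= 0 or qs <= 0:
        raise ValueError("zero-sum density")
    bc = np.sum(np.sqrt((p / ps) * (q / qs)))
    return float(np.clip(np.sqrt(max(1.0 - bc, 0.0)), 0.0, 1.0))


def _coords_lookup(coords) -> dict[str, np.ndarray]:
    if isinstance(coords, pd.DataFrame):
        if "channel" in coords.columns:
            return {r.channel: np.array([r.x, r.y, r.z])
                    for r in coords.itertuples()}
        return {str(i): np.asarray(row[["x", "y", "z"]], dtype=float)
                for i, row in coords.iterrows()}
    return {k: np.asarray(v, dtype=float) for k, v in coords.items()}


def _segment_matrix(segs) -> np.ndarray:
    """Accept a SegmentSet or a (n_segments, length) array."""
    if hasattr(segs, "segments"):
        return np.asarray(segs.segments, dtype=np.float64)
    arr = np.asarray(segs, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None]
    return arr


def match_channels(eeg_segs: Mapping[str, object], seeg_segs: Mapping[str, object],
                   coords, rate: float, bin_mm: float = DEFAULT_BIN_MM,
                   nperseg: int = WELCH_NPERSEG) -> MatchResult:
    """Interval-regression matching of scalp to depth channels.

    ``eeg_segs``/``seeg_segs`` map channel names to SegmentSets (or arrays of
    shape (n_segments, length)) with synchronized windows; ``coords`` maps
    every channel name to its millimetre position.
    """
    pos = _coords_lookup(coords)
    eeg_names = sorted(eeg_segs)
    seeg_names = sorted(seeg_segs)
    missing = [c for c in eeg_names + seeg_names if c not in pos]
    if missing:
        raise ValueError(f"missing coordinates for channels: {missing}")

    eeg_mat = {c: _segment_matrix(eeg_segs[c]) for c in eeg_names}
    seeg_mat = {c: _segment_matrix(seeg_segs[c]) for c in seeg_names}
    n_seg = min(min(m.shape[0] for m in eeg_mat.values()),
                min(m.shape[0] for m in seeg_mat.values()))

    dist = {(e, s): float(np.linalg.norm(pos[e] - pos[s]))
            for e in eeg_names for s in seeg_names}

    # PSD cache: (channel, segment index) -> normalized PSD
    def psds(mat):
        out = {}
        for c, m in mat.items():
            for t in range(n_seg):
                _, p = welch_psd(m[t], rate, nperseg)
                out[(c, t)] = p
        return out

    psd_e, psd_s = psds(eeg_mat), psds(seeg_mat)

    hd_sum = {k: 0.0 for k in dist}
    bin_positive: dict[int, int] = {}
    bin_total: dict[int, int] = {}
    bin_slopes: dict[int, list[float]] = {}
    bin_pairs: dict[int, set] = {}

    for e in eeg_names:
        d_vec = np.array([dist[(e, s)] for s in seeg_names])
        bins = np.floor(d_vec / bin_mm).astype(int)
        for t in range(n_seg):
            hd_vec = np.array([
                hellinger_distance(psd_e[(e, t)], psd_s[(s, t)])
                for s in seeg_names
            ])
            for s, h in zip(seeg_names, hd_vec):
                hd_sum[(e, s)] += h
            for b in np.unique(bins):
                idx = bins == b
                if idx.sum() < 2:
                    continue
                slope = np.polyfit(d_vec[idx], hd_vec[idx], 1)[0]
                bin_total[b] = bin_total.get(b, 0) + 1
                bin_positive[b] = bin_positive.get(b, 0) + int(slope > 0)
                bin_slopes.setdefault(b, []).append(float(slope))
                bin_pairs.setdefault(b, set()).update(
                    (e, s) for s, i in zip(seeg_names, idx) if i)

    if not bin_total:
        raise RuntimeError("no distance interval holds at least two candidate "
                           "pairs; decrease bin_mm granularity or add channels")

    per_interval = [
        IntervalStats(
            low=b * bin_mm, high=(b + 1) * bin_mm,
            n_pairs=len(bin_pairs[b]), n_slopes=bin_total[b],
            positive_fraction=bin_positive[b] / bin_total[b],
            mean_slope=float(np.mean(bin_slopes[b])),
        )
        for b in sorted(bin_total)
    ]
    best = max(per_interval, key=lambda iv: (iv.positive_fraction, -iv.low))
    a = best.low

    # pair each scalp channel to the unused depth channel nearest to a
    used: set[str] = set()
    pairs = []
    for e in eeg_names:
        avail = [s for s in seeg_names if s not in used]
        if not avail:
            warnings.warn("fewer depth than scalp channels; partial pairing")
            break
        s_best = min(avail, key=lambda s: (abs(dist[(e, s)] - a), dist[(e, s)], s))
        pairs.append((e, s_best))
        used.add(s_best)

    candidates = [
        CandidatePair(e, s, dist[(e, s)], hd_sum[(e, s)] / n_seg)
        for e in eeg_names for s in seeg_names
    ]
    return MatchResult(itv_star=(best.low, best.high), per_interval=per_interval,
                       pairs=pairs, candidates=candidates)


def nearest_neighbor_match(eeg_coords: Mapping[str, object],
                           seeg_coords: Mapping[str, object]
                           ) -> list[tuple[str, str]]:
    """Greedy global assignment by smallest remaining distance.

    Ties broken lexicographically by (scalp name, depth name); depth
    channels are not reused. With fewer depth than scalp channels the
    assignment is partial and a warning is raised.
    """
    epos = _coords_lookup(eeg_coords)
    spos = _coords_lookup(seeg_coords)
    edges = sorted(
        (float(np.linalg.norm(ep - sp)), e, s)
        for e, ep in epos.items() for s, sp in spos.items()
    )
    pairs, used_e, used_s = [], set(), set()
    for d, e, s in edges:
        if e in used_e or s in used_s:
            continue
        pairs.append((e, s))
        used_e.add(e)
        used_s.add(s)
    if len(pairs) < len(epos):
        warnings.warn("fewer depth than scalp channels; partial assignment")
    return sorted(pairs)
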