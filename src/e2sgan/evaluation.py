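"""Temporal and spectral distance metrics and baseline-normalized scores.

Generated depth segments are scored against the simultaneous real depth
segments three ways — dynamic time warping in the time domain, and RMSE and
Hellinger distance of Welch power spectral densities in the frequency
domain — then normalized against the raw scalp-input baseline by a binary
log-ratio: negative values mean the synthesis is closer to the real depth
signal than the scalp input was. All three raw metrics are
smaller-is-better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .matching import hellinger_distance, welch_psd

METRICS = ("dtw", "psd_rmse", "hd")
_PSD_FLOOR = 1e-300


@njit(cache=False)
def _dtw_dp(a, b):  # pragma: no cover - numba-compiled
    n, m = a.shape[0], b.shape[0]
    d = np.empty((n + 1, m + 1))
    d[:] = np.inf
    d[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = abs(a[i - 1] - b[j - 1])
            best = d[i - 1, j - 1]
            if d[i - 1, j] < best:
                best = d[i - 1, j]
            if d[i, j - 1] < best:
                best = d[i, j - 1]
            d[i, j] = c + best
    return d[n, m]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classic dynamic-programming warping cost.

    Absolute-difference local cost with steps {(1,0), (0,1), (1,1)}; no
    bandwidth constraint. Symmetric in its arguments.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty series")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("series must be finite")
    return float(_dtw_dp(a, b))


def spectral_metrics(s_fake: np.ndarray, s_real: np.ndarray, rate: float,
                     nperseg: int = 256) -> tuple[float, float]:
    """(PSD RMSE, Hellinger distance) between two equal-length segments."""
    s_fake = np.asarray(s_fake, dtype=np.float64)
    s_real = np.asarray(s_real, dtype=np.float64)
    if s_fake.shape != s_real.shape:
        raise ValueError("segments must have equal length")
    _, p_fake = welch_psd(s_fake, rate, nperseg)
    _, p_real = welch_psd(s_real, rate, nperseg)
    psd_rmse = float(np.sqrt(np.mean((p_fake - p_real) ** 2)))
    if p_fake.sum() <= 0 or p_real.sum() <= 0:
        warnings.warn("degenerate (all-zero) signal; flooring PSD")
        p_fake = np.maximum(p_fake, _PSD_FLOOR)
        p_real = np.maximum(p_real, _PSD_FLOOR)
    hd = hellinger_distance(p_fake, p_real)
    return psd_rmse, hd


def log_ratio(eval_fake: float, eval_baseline: float) -> float:
    """Binary log of the metric ratio against the scalp-input baseline."""
    if eval_baseline <= 0:
        raise ValueError("baseline evaluation must be positive")
    return float(np.log2(eval_fake / eval_baseline))


@dataclass
class EvalReport:
    """Per-segment raw metrics, baselines, log-ratios and aggregates."""

    table: pd.DataFrame          # per-segment raw metrics, fake and baseline
    baselines: dict[str, float]  # mean raw metric of (scalp input, real depth)
    log_table: pd.DataFrame      # per-segment log-ratios
    aggregate: pd.DataFrame      # mean +/- std of the log-ratios

    def summary(self) -> str:
        parts = []
        for m in METRICS:
            mean = self.aggregate.loc[m, "mean"]
            std = self.aggregate.loc[m, "std"]
            parts.append(f"{m.upper()}/{self.baselines[m]:.3e}: "
                         f"{mean:.3f} +/- {std:.3f}")
        return "\n".join(parts)


def evaluate_segments(fake: np.ndarray, real: np.ndarray, eeg: np.ndarray,
                      rate: float, nperseg: int = 256) -> EvalReport:
    """Score generated depth segments against real ones, scalp as baseline.

    ``fake``, ``real`` and ``eeg`` are (n_segments, length) arrays of
    time-domain reconstructions with synchronized windows.
    """
    fake, real, eeg = (np.asarray(x, dtype=np.float64) for x in (fake, real, eeg))
    if not (fake.shape == real.shape == eeg.shape):
        raise ValueError("fake, real and scalp arrays must share a shape")
    rows, base_rows = [], []
    for i in range(fake.shape[0]):
        pf, hf = spectral_metrics(fake[i], real[i], rate, nperseg)
        pb, hb = spectral_metrics(eeg[i], real[i], rate, nperseg)
        rows.append({"segment": i, "dtw": dtw_distance(fake[i], real[i]),
                     "psd_rmse": pf, "hd": hf})
        base_rows.append({"segment": i, "dtw": dtw_distance(eeg[i], real[i]),
                          "psd_rmse": pb, "hd": hb})
    table = pd.DataFrame(rows).set_index("segment")
    base = pd.DataFrame(base_rows).set_index("segment")
    baselines = {m: float(base[m].mean()) for m in METRICS}
    log_table = pd.DataFrame({
        m: [log_ratio(v, baselines[m]) for v in table[m]] for m in METRICS
    }, index=table.index)
    aggregate = pd.DataFrame({
        "mean": log_table.mean(), "std": log_table.std(ddof=0)
    })
    return EvalReport(table=table, baselines=baselines, log_table=log_table,
                      aggregate=aggregate)


@dataclass
class RobustnessProfile:
    widths: np.ndarray           # sub-segment lengths, 2 .. L // 2
    std_per_width: np.ndarray    # STD of sub-segment RMSEs at each width
    pooled: np.ndarray           # all sub-segment RMSEs pooled across widths


def robustness_profile(s_fake: np.ndarray, s_real: np.ndarray) -> RobustnessProfile:
    """Sub-segment RMSE dispersion across window widths.

    For each width w from 2 to L/2 both signals are split into floor(L/w)
    non-overlapping sub-segments; the STD of per-sub-segment RMSEs measures
    how evenly the synthesis error is distributed in time (spiky errors
    inflate it at small widths).
    """
    s_fake = np.asarray(s_fake, dtype=np.float64)
    s_real = np.asarray(s_real, dtype=np.float64)
    if s_fake.shape != s_real.shape:
        raise ValueError("equal lengths required")
    n = s_fake.size
    if n < 4:
        raise ValueError("signals must have at least 4 samples")
    widths, stds, pooled = [], [], []
    err2 = (s_fake - s_real) ** 2
    for w in range(2, n // 2 + 1):
        k = n // w
        sub = err2[: k * w].reshape(k, w)
        rmse = np.sqrt(sub.mean(axis=1))
        widths.append(w)
        stds.append(rmse.std(ddof=0))
        pooled.append(rmse)
    return RobustnessProfile(widths=np.array(widths),
                             std_per_width=np.array(stds),
                             pooled=np.concatenate(pooled))
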