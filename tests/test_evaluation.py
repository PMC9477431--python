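"""Distance metrics, baseline-normalized scores, robustness profiles."""

import numpy as np
import pytest

from e2sgan.evaluation import (
    dtw_distance,
    evaluate_segments,
    log_ratio,
    robustness_profile,
    spectral_metrics,
)


def dtw_oracle(a, b):
    """Exhaustive minimum over all monotone warping paths (tiny inputs)."""
    n, m = len(a), len(b)
    best = {}

    def visit(i, j):
        if (i, j) in best:
            return best[(i, j)]
        c = abs(a[i] - b[j])
        if i == 0 and j == 0:
            r = c
        else:
            prev = []
            if i > 0:
                prev.append(visit(i - 1, j))
            if j > 0:
                prev.append(visit(i, j - 1))
            if i > 0 and j > 0:
                prev.append(visit(i - 1, j - 1))
            r = c + min(prev)
        best[(i, j)] = r
        return r

    return visit(n - 1, m - 1)


class TestDtw:
    def test_identical_series_cost_zero(self, rng):
        a = rng.standard_normal(50)
        assert dtw_distance(a, a) == 0.0

    def test_constant_offset_diagonal_path(self):
        assert dtw_distance([0.0, 0.0, 0.0], [1.0, 1.0, 1.0]) == pytest.approx(3.0)

    def test_symmetry(self, rng):
        a, b = rng.standard_normal(30), rng.standard_normal(25)
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dtw_distance([], [1.0])

    def test_matches_exhaustive_oracle_on_short_series(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 9))
            m = int(rng.integers(1, 9))
            a = rng.standard_normal(n)
            b = rng.standard_normal(m)
            assert dtw_distance(a, b) == pytest.approx(dtw_oracle(a, b),
                                                       rel=1e-12)


class TestSpectralMetrics:
    def test_identical_segments_give_zero(self, segment_factory):
        x = segment_factory()
        rmse, hd = spectral_metrics(x, x, 64.0)
        assert rmse == 0.0
        assert hd == pytest.approx(0.0, abs=1e-9)

    def test_scaling_cancels_in_hellinger_not_rmse(self, segment_factory):
        x = segment_factory()
        rmse, hd = spectral_metrics(2 * x, x, 64.0)
        assert hd == pytest.approx(0.0, abs=1e-9)
        assert rmse > 0.0

    def test_white_vs_narrowband_in_open_interval(self, rng):
        white = rng.standard_normal(1016)
        narrow = np.sin(2 * np.pi * 10 * np.arange(1016) / 64.0)
        _, hd = spectral_metrics(white, narrow, 64.0)
        assert 0.0 < hd < 1.0
        # cross-check against the closed form on the PSD vectors
        from e2sgan.matching import hellinger_distance, welch_psd
        _, p = welch_psd(white, 64.0)
        _, q = welch_psd(narrow, 64.0)
        assert hd == pytest.approx(hellinger_distance(p, q), rel=1e-12)

    def test_degenerate_signal_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            spectral_metrics(np.zeros(1016), np.ones(1016) * 0.0, 64.0)


class TestLogRatio:
    def test_equal_metrics_give_zero(self):
        assert log_ratio(0.7, 0.7) == 0.0

    def test_doubling_and_halving(self):
        assert log_ratio(2.0, 1.0) == pytest.approx(1.0)
        assert log_ratio(0.5, 1.0) == pytest.approx(-1.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            log_ratio(1.0, 0.0)

    def test_monotone_in_first_argument(self, rng):
        base = 0.3
        vals = np.sort(rng.uniform(0.01, 2.0, 10))
        scores = [log_ratio(v, base) for v in vals]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_mean_of_scores_matches_independent_recomputation(self, rng):
        ratios = np.exp(rng.uniform(np.log(0.2), np.log(5.0), 200))
        base = 0.9
        mean_scores = np.mean([log_ratio(r * base, base) for r in ratios])
        assert mean_scores == pytest.approx(np.mean(np.log2(ratios)), rel=1e-9)


class TestRobustnessProfile:
    def test_identical_signals_give_zero_stds(self, rng):
        x = rng.standard_normal(64)
        prof = robustness_profile(x, x)
        assert np.all(prof.std_per_width == 0.0)
        assert list(prof.widths) == list(range(2, 33))

    def test_constant_error_gives_zero_stds(self, rng):
        x = rng.standard_normal(64)
        prof = robustness_profile(x + 1.3, x)
        assert np.allclose(prof.std_per_width, 0.0, atol=1e-12)

    def test_injected_spike_raises_small_width_std(self, rng):
        x = rng.standard_normal(256)
        clean = x + 0.01 * rng.standard_normal(256)
        spiky = clean.copy()
        spiky[100] += 5.0
        p_clean = robustness_profile(clean, x)
        p_spiky = robustness_profile(spiky, x)
        assert p_spiky.std_per_width[0] > p_clean.std_per_width[0]

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            robustness_profile(np.zeros(3), np.zeros(3))


class TestEvalReport:
    def test_report_structure_and_sign_convention(self, rng, segment_factory):
        real = np.stack([segment_factory() for _ in range(3)])
        eeg = real + 0.5 * rng.standard_normal(real.shape)
        fake = real + 0.05 * rng.standard_normal(real.shape)
        rep = evaluate_segments(fake, real, eeg, rate=64.0)
        assert list(rep.table.columns) == ["dtw", "psd_rmse", "hd"]
        assert set(rep.aggregate.columns) == {"mean", "std"}
        # a synthesis much closer to the target than the scalp input scores
        # negative on every log-ratio
        assert (rep.aggregate["mean"] < 0).all()
        assert "DTW" in rep.summary()

    def test_fake_equal_to_eeg_scores_near_zero(self, rng, segment_factory):
        real = np.stack([segment_factory() for _ in range(3)])
        eeg = real + 0.3 * rng.standard_normal(real.shape)
        rep = evaluate_segments(eeg, real, eeg, rate=64.0)
        # identical fake and baseline: mean log-ratio 0 up to per-segment
        # baseline spread
        assert np.allclose(rep.aggregate["mean"], 0.0, atol=0.2)
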