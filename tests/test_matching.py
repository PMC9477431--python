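"""Hellinger distance and the interval-regression matching strategy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from e2sgan.matching import (
    hellinger_distance,
    match_channels,
    nearest_neighbor_match,
)
from e2sgan.preprocess import segment_recording
from e2sgan.synthetic import SourceModel, make_paired_recording
from conftest import line_geometry


class TestHellingerDistance:
    def test_identical_distributions_give_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert hellinger_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_one(self):
        assert hellinger_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # sqrt(1 - (sqrt(0.45) + sqrt(0.05)))
        expected = np.sqrt(1 - (np.sqrt(0.5 * 0.9) + np.sqrt(0.5 * 0.1)))
        assert hellinger_distance([0.5, 0.5], [0.9, 0.1]) \
            == pytest.approx(expected, rel=1e-12)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError, match="zero-sum"):
            hellinger_distance([0.0, 0.0], [0.5, 0.5])

    def test_unnormalized_inputs_are_normalized(self):
        a = np.array([2.0, 6.0])
        b = np.array([1.0, 3.0])
        assert hellinger_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 16)
        q = rng.uniform(0, 1, 16)
        p[0] += 1e-6
        q[0] += 1e-6
        d1 = hellinger_distance(p, q)
        d2 = hellinger_distance(q, p)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0.0 <= d1 <= 1.0


from e2sgan.surrogate import MATCHING_BIN_MM as MONOTONE_BIN_MM
from e2sgan.surrogate import matching_benchmark


def monotone_scenario(seed=0, exception=None):
    """The package's distance-monotone benchmark, with raw pieces exposed."""
    pr, res = matching_benchmark(seed, exception=exception)
    coords = dict(pr.eeg.coords)
    coords.update(pr.seeg.coords)
    return pr, segment_recording(pr.eeg), segment_recording(pr.seeg), coords


@pytest.fixture(scope="module")
def monotone_match():
    pr, res = matching_benchmark(0)
    coords = dict(pr.eeg.coords)
    coords.update(pr.seeg.coords)
    return pr, coords, res


class TestMatchChannels:
    def test_monotone_coupling_gives_all_positive_intervals(self, monotone_match):
        _, _, res = monotone_match
        assert len(res.per_interval) >= 3
        for iv in res.per_interval:
            assert iv.positive_fraction == 1.0

    def test_itv_star_is_lowest_interval_on_ties(self, monotone_match):
        _, _, res = monotone_match
        lows = [iv.low for iv in res.per_interval
                if iv.positive_fraction == 1.0]
        assert res.itv_star[0] == min(lows)

    def test_truth_pairs_recovered(self, monotone_match):
        pr, _, res = monotone_match
        assert set(pr.truth_pairs) <= set(res.pairs)

    def test_candidate_similarity_increases_with_distance(self, monotone_match):
        _, _, res = monotone_match
        for e in ("E01", "E02"):
            cands = sorted((c for c in res.candidates if c.eeg_channel == e),
                           key=lambda c: c.distance_mm)
            hds = [c.similarity for c in cands]
            assert all(a < b for a, b in zip(hds, hds[1:]))

    def test_single_depth_channel_matches_everything(self):
        m = SourceModel(noise_sd=0.1, seed=0)
        pr = make_paired_recording(m, 2, 1, 64.0, 64.0,
                                   geometry=line_geometry(n_seeg=1))
        esegs = segment_recording(pr.eeg)
        ssegs = segment_recording(pr.seeg)
        coords = dict(pr.eeg.coords)
        coords.update(pr.seeg.coords)
        with pytest.raises(RuntimeError, match="at least two"):
            match_channels(esegs, ssegs, coords, rate=64.0, bin_mm=MONOTONE_BIN_MM)
        # a single candidate cannot form an interval regression, but the
        # nearest-neighbour variant still assigns it
        pairs = nearest_neighbor_match(pr.eeg.coords, pr.seeg.coords)
        assert pairs[0][1] == "S01"

    def test_missing_coordinates_rejected(self, monotone_match):
        pr, coords, _ = monotone_match
        esegs = segment_recording(pr.eeg)
        ssegs = segment_recording(pr.seeg)
        bad = {k: v for k, v in coords.items() if k != "S03"}
        with pytest.raises(ValueError, match="missing coordinates"):
            match_channels(esegs, ssegs, bad, rate=64.0, bin_mm=MONOTONE_BIN_MM)

    def test_exception_link_decreases_affected_interval_slope(self, monotone_match):
        pr, coords, base = monotone_match
        d = {s: np.linalg.norm(coords["E01"] - coords[s])
             for s in pr.seeg.channel_names}
        far = max(d, key=d.get)
        _, pert = matching_benchmark(0, exception=[("E01", far, 1.5)])
        low = MONOTONE_BIN_MM * (d[far] // MONOTONE_BIN_MM)
        s_base = [iv for iv in base.per_interval if iv.low == low][0]
        s_pert = [iv for iv in pert.per_interval if iv.low == low][0]
        assert s_pert.mean_slope < s_base.mean_slope

    def test_result_invariant_to_channel_ordering(self, monotone_match):
        pr, coords, res = monotone_match
        esegs = segment_recording(pr.eeg)
        ssegs = segment_recording(pr.seeg)
        shuffled_e = dict(reversed(list(esegs.items())))
        shuffled_s = dict(reversed(list(ssegs.items())))
        res2 = match_channels(shuffled_e, shuffled_s, coords, rate=64.0,
                              bin_mm=MONOTONE_BIN_MM)
        assert res2.itv_star == res.itv_star
        assert res2.pairs == res.pairs


class TestNearestNeighbor:
    def test_single_pair(self):
        pairs = nearest_neighbor_match({"E1": [0, 0, 0]}, {"S1": [1, 0, 0]})
        assert pairs == [("E1", "S1")]

    def test_greedy_order_beats_row_wise_assignment(self):
        # distance matrix [[1, 2], [1.5, 10]]: greedy takes (E1,S1)=1 first,
        # leaving (E2,S2)=10 — exactly the documented greedy behaviour
        eeg = {"E1": [0.0, 0, 0], "E2": [0.0, 1, 0]}
        seeg = {"S1": [1.0, 0, 0], "S2": [2.0, 0, 0]}
        d = {(e, s): np.linalg.norm(np.array(eeg[e]) - np.array(seeg[s]))
             for e in eeg for s in seeg}
        assert d[("E1", "S1")] < d[("E2", "S1")] < d[("E1", "S2")]
        pairs = nearest_neighbor_match(eeg, seeg)
        assert pairs == [("E1", "S1"), ("E2", "S2")]

    def test_tied_distances_break_deterministically(self):
        eeg = {"E1": [0, 0, 0], "E2": [2, 0, 0]}
        seeg = {"S1": [1, 0, 0], "S2": [1, 0, 0.0]}
        # both scalp channels are equidistant from both depth channels:
        # lexicographic tie-break pairs E1-S1, E2-S2
        assert nearest_neighbor_match(eeg, seeg) == [("E1", "S1"), ("E2", "S2")]

    def test_partial_assignment_warns(self):
        eeg = {"E1": [0, 0, 0], "E2": [2, 0, 0]}
        seeg = {"S1": [1, 0, 0]}
        with pytest.warns(UserWarning, match="partial"):
            pairs = nearest_neighbor_match(eeg, seeg)
        assert len(pairs) == 1
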