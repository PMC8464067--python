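"""Peak-calling unit tests: coverage, noise floor, borders, pairing, filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exoregulon import io, synth
from exoregulon.peaks import (
    BorderCall,
    ExoPeak,
    StrandCoverage,
    build_strand_coverage,
    detect_borders,
    filter_and_combine,
    noise_floor,
    normalize_depth,
    pair_borders,
    score_snr,
)


class TestStrandCoverage:
    def test_build_from_intervals(self):
        t = build_strand_coverage([(0, 3, 2), (3, 5, 1)], genome_length=10)
        assert list(t.values[:6]) == [2, 2, 2, 1, 1, 0]
        assert t.library_size == 8

    def test_empty_track(self):
        t = build_strand_coverage([], genome_length=5)
        assert t.library_size == 0

    def test_bedgraph_round_trip(self, tmp_path, small_dataset):
        track = small_dataset.tracks["ip1"]["+"]
        path = tmp_path / "t.bedGraph"
        io.write_bedgraph(path, track.values)
        back = io.read_bedgraph(path, len(track.values))
        np.testing.assert_array_equal(back, track.values)

    def test_out_of_range_interval_rejected(self):
        with pytest.raises(ValueError, match="record 0"):
            build_strand_coverage([(0, 20, 1)], genome_length=10)
        with pytest.raises(ValueError, match="negative"):
            build_strand_coverage([(0, 2, -1)], genome_length=10)


class TestNormalizeDepth:
    def test_scales_to_target(self):
        a = StrandCoverage("a", "+", np.full(10, 1.0))  # lib 10
        b = StrandCoverage("b", "+", np.full(10, 2.0))  # lib 20
        na, nb = normalize_depth([a, b], target_depth=10)
        assert na.library_size == pytest.approx(10)
        assert nb.library_size == pytest.approx(10)
        np.testing.assert_allclose(nb.values, a.values)

    def test_equal_libraries_unchanged(self):
        a = StrandCoverage("a", "+", np.full(10, 3.0))
        (na,) = normalize_depth([a], target_depth=30)
        np.testing.assert_allclose(na.values, a.values)

    def test_snr_invariant_under_common_scaling(self):
        rng = np.random.default_rng(0)
        ip = [StrandCoverage("ip", s, rng.poisson(2, 200).astype(float)) for s in "+-"]
        mock = [StrandCoverage("mock", s, rng.poisson(2, 200).astype(float)) for s in "+-"]
        peak = ExoPeak(50, 90)
        base = score_snr(peak, ip, mock, pseudocount=0)
        scaled = score_snr(
            peak, [t.scaled(3) for t in ip], [t.scaled(3) for t in mock], pseudocount=0
        )
        assert scaled == pytest.approx(base)


class TestNoiseFloor:
    def test_distinct_values_1_to_100(self):
        vals = np.zeros(500)
        vals[:100] = np.arange(1, 101)
        assert noise_floor(vals, 0.05) == 96

    def test_constant_track(self):
        assert noise_floor(np.full(50, 7.0)) == 7.0

    def test_full_fraction_gives_min_nonzero(self):
        vals = np.array([0, 4, 2, 9, 0, 3], dtype=float)
        assert noise_floor(vals, 1.0) == 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            noise_floor(np.zeros(10))

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=60),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_at_most_fraction_exceed(self, vals, frac):
        arr = np.array(vals, dtype=float)
        thr = noise_floor(arr, frac)
        assert thr in arr
        assert (arr > thr).sum() <= frac * len(arr)


class TestDetectBorders:
    def test_single_spike(self):
        vals = np.zeros(100)
        vals[40] = 10
        t = StrandCoverage("s", "+", vals)
        calls = detect_borders(t, smoothing_window=1, min_height=1)
        assert [c.position for c in calls] == [40]

    def test_plateau_reports_leftmost(self):
        vals = np.zeros(100)
        vals[30:35] = 5
        t = StrandCoverage("s", "+", vals)
        calls = detect_borders(t, smoothing_window=1, min_height=1)
        assert [c.position for c in calls] == [30]

    def test_even_window_rejected(self):
        t = StrandCoverage("s", "+", np.ones(10))
        with pytest.raises(ValueError, match="odd"):
            detect_borders(t, smoothing_window=4, min_height=1)

    def test_simulated_borders_recovered_within_5_bases(self):
        # truth-table oracle over many seeds: >= 95% of borders within +-5
        import pandas as pd

        centers = np.arange(1000, 40_000, 800)[:20]
        model = synth.ReadModel(reads_per_site=200, background_rate=0.001, border_jitter_sd=3)
        ok = total = 0
        for seed in range(20):
            tracks = synth.simulate_exo_coverage(
                pd.DataFrame({"center": centers}), model, 40_000, n_replicates=1, seed=seed
            )
            fb = [b.position for b in detect_borders(tracks["ip1"]["+"], min_height=2.0)]
            for c in centers:
                truth = c - model.border_offset
                ok += any(abs(p - truth) <= 5 for p in fb)
                total += 1
        assert ok / total >= 0.95


def _max_matching_bruteforce(fwd, rev, d_min, d_max):
    """Exhaustive maximum bimodal pairing size (oracle for small inputs)."""

    def go(i, used):
        if i == len(fwd):
            return 0
        best = go(i + 1, used)  # leave fwd[i] unpaired
        for j, r in enumerate(rev):
            if j not in used and d_min <= r - fwd[i] <= d_max:
                best = max(best, 1 + go(i + 1, used | {j}))
        return best

    return go(0, frozenset())


class TestPairBorders:
    def test_basic_pairing(self):
        fwd = [BorderCall("+", 100, 5.0)]
        rev = [BorderCall("-", 140, 5.0)]
        (peak,) = pair_borders(fwd, rev, d_min=5, d_max=100)
        assert (peak.center, peak.width) == (120, 40)

    def test_wrong_orientation_not_bimodal(self):
        fwd = [BorderCall("+", 140, 5.0)]
        rev = [BorderCall("-", 100, 5.0)]
        assert pair_borders(fwd, rev) == []

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            nf, nr = rng.integers(0, 7, size=2)
            fwd_pos = sorted(rng.choice(200, size=nf, replace=False))
            rev_pos = sorted(rng.choice(200, size=nr, replace=False))
            fwd = [BorderCall("+", int(p), 1.0) for p in fwd_pos]
            rev = [BorderCall("-", int(p), 1.0) for p in rev_pos]
            got = len(pair_borders(fwd, rev, d_min=5, d_max=60))
            want = _max_matching_bruteforce(fwd_pos, rev_pos, 5, 60)
            assert got == want


class TestScoreSnr:
    def _tracks(self, ip_window_sum, mock_window_sum, width=30):
        ip_vals = np.zeros(200)
        mock_vals = np.zeros(200)
        ip_vals[50:50 + width] = ip_window_sum / width
        mock_vals[50:50 + width] = mock_window_sum / width
        ip = [StrandCoverage("ip", "+", ip_vals), StrandCoverage("ip", "-", np.zeros(200))]
        mock = [StrandCoverage("mock", "+", mock_vals), StrandCoverage("mock", "-", np.zeros(200))]
        return ip, mock

    def test_ip_over_mock_ratio(self):
        ip, mock = self._tracks(30, 20)
        peak = ExoPeak(50, 79)
        assert score_snr(peak, ip, mock, pseudocount=0) == pytest.approx(1.5)

    def test_zero_mock_with_pseudocount_is_finite(self):
        ip, mock = self._tracks(10, 0)
        peak = ExoPeak(50, 79)
        assert score_snr(peak, ip, mock, pseudocount=1) == pytest.approx(10)

    def test_floor_mode_uses_border_signal(self):
        vals = np.zeros(200)
        vals[100] = 10  # forward border spike
        vals2 = np.zeros(200)
        vals2[140] = 10
        ip = [StrandCoverage("ip", "+", vals), StrandCoverage("ip", "-", vals2)]
        peak = ExoPeak(100, 140)
        # mean over two 5-position border neighborhoods = 20/10 = 2
        assert score_snr(peak, ip, reference=1.0) == pytest.approx(2.0)

    def test_nonpositive_floor_rejected(self):
        ip, _ = self._tracks(10, 0)
        with pytest.raises(ValueError):
            score_snr(ExoPeak(50, 79), ip, reference=0.0)


class TestFilterAndCombine:
    def _peak(self, center, snr, width=40):
        return ExoPeak(center - width // 2, center + width // 2, snr=snr)

    def test_low_snr_removed(self):
        cands = {"a": [self._peak(100, 1.49)], "b": [self._peak(100, 5.0)]}
        assert filter_and_combine(cands) == []

    def test_snr_exactly_at_threshold_retained(self):
        cands = {"a": [self._peak(100, 1.5)], "b": [self._peak(100, 1.5)]}
        (peak,) = filter_and_combine(cands)
        assert peak.snr == 1.5 and peak.passed_filters

    def test_single_replicate_peak_removed(self):
        cands = {"a": [self._peak(100, 9.0)], "b": []}
        assert filter_and_combine(cands) == []

    def test_merged_coordinates_are_means(self):
        cands = {"a": [self._peak(100, 2.0)], "b": [self._peak(110, 3.0)]}
        (peak,) = filter_and_combine(cands, match_tolerance=20)
        assert peak.center == 105
        assert peak.snr == 2.0
        assert peak.replicate_support == frozenset(["a", "b"])


def test_final_peaks_satisfy_all_invariants(small_dataset):
    from exoregulon.pipeline import call_peaks_from_tracks, make_config

    cfg = make_config({})["peaks"]
    final = call_peaks_from_tracks(small_dataset.tracks, cfg)
    assert final, "no peaks called on the default small dataset"
    n_reps = len([s for s in small_dataset.tracks if s != "mock"])
    for p in final:
        assert p.fwd_border < p.rev_border
        assert cfg["d_min"] <= p.width <= cfg["d_max"]
        assert p.snr >= cfg["snr_min"]
        assert len(p.replicate_support) == n_reps
        assert p.passed_filters


def test_global_rescaling_leaves_final_peaks_unchanged(small_dataset):
    from exoregulon.pipeline import call_peaks_from_tracks, make_config

    cfg = make_config({})["peaks"]
    base = call_peaks_from_tracks(small_dataset.tracks, cfg)
    scaled = {
        s: {st_: t.scaled(2.5) for st_, t in pair.items()}
        for s, pair in small_dataset.tracks.items()
    }
    again = call_peaks_from_tracks(scaled, cfg)
    assert [(p.fwd_border, p.rev_border) for p in base] == [
        (p.fwd_border, p.rev_border) for p in again
    ]
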