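import numpy as np
import pytest

from ibdscan.scan import (
    UNDERFLOW,
    call_regions,
    count_significant_windows,
    max_min_statistic,
)
from ibdscan.scan import test_positions as reject_calls  # avoid pytest collection
from ibdscan.validation import simulate_ou_genome


def null_track(n_cm=100.0, delta=0.02, seed=0, chroms=1):
    return simulate_ou_genome(
        50.0, [n_cm] * chroms, delta, np.random.default_rng(seed)
    )


class TestTestPositions:
    def test_boundary_value_fails_to_reject(self):
        track = null_track()
        track.z[:] = 0.0
        track.z[10] = 4.0
        calls = reject_calls(track, 4.0)
        assert not calls.any()          # equality goes to the null

    def test_strict_exceedance_rejects(self):
        track = null_track()
        track.z[:] = 0.0
        track.z[10] = 4.0 + 1e-9
        calls = reject_calls(track, 4.0)
        assert calls.sum() == 1 and calls[10]


class TestCallRegions:
    def _track_with_run(self, run_len, start=100):
        track = null_track()
        track.z[:] = 0.0
        track.z[start:start + run_len] = 5.0
        track.rates[:] = track.z
        return track

    def test_run_below_span_floor_not_reported(self):
        track = self._track_with_run(24)     # (24-1)*0.02 = 0.46 cM
        calls = reject_calls(track, 4.0)
        assert call_regions(track, calls, min_span_cm=0.5) == []

    def test_run_above_span_floor_reported(self):
        track = self._track_with_run(27)     # (27-1)*0.02 = 0.52 cM
        calls = reject_calls(track, 4.0)
        regions = call_regions(track, calls, min_span_cm=0.5)
        assert len(regions) == 1
        assert regions[0].span_cm == pytest.approx(0.52)

    def test_peak_fields_point_at_maximum_rate(self):
        track = self._track_with_run(30, start=50)
        track.rates[60] = 9.0   # peak inside the run
        track.z[60] = 9.0
        calls = reject_calls(track, 4.0)
        (region,) = call_regions(track, calls)
        assert region.peak_rate == 9.0
        assert region.start_bp <= region.peak_bp <= region.end_bp
        assert region.peak_z > 4.0

    def test_extreme_peak_reports_underflow(self):
        track = self._track_with_run(30)
        track.z[track.z > 0] = 40.0          # sf(40) underflows to 0.0
        calls = reject_calls(track, 4.0)
        (region,) = call_regions(track, calls)
        assert region.p_value == UNDERFLOW

    def test_single_gap_splits_regions(self):
        track = self._track_with_run(60, start=100)
        track.z[130] = 0.0                    # one sub-threshold point
        calls = reject_calls(track, 4.0)
        regions = call_regions(track, calls, min_span_cm=0.5)
        assert len(regions) == 2

    def test_region_count_monotone_in_threshold_and_floor(self, rng):
        track = simulate_ou_genome(30.0, [100.0] * 4, 0.05, rng)
        prev = None
        for z_star in (1.5, 2.0, 2.5, 3.0):
            n = len(call_regions(track, reject_calls(track, z_star),
                                 min_span_cm=0.2))
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for floor in (0.1, 0.3, 0.5, 1.0):
            n = len(call_regions(track, reject_calls(track, 1.5),
                                 min_span_cm=floor))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_regions_reproduce_rejected_runs(self, rng):
        """Reported regions are exactly the rejected runs of span >= floor."""
        track = simulate_ou_genome(30.0, [100.0] * 2, 0.05, rng)
        z_star = 2.0
        calls = reject_calls(track, z_star)
        regions = call_regions(track, calls, min_span_cm=0.0)
        total_from_regions = sum(
            int(round(r.span_cm / track.grid.delta_cm)) + 1 for r in regions
        )
        assert total_from_regions == int(calls.sum())
        for r in regions:
            assert r.peak_z > z_star


class TestMaxMin:
    def test_window_one_is_plain_maximum(self):
        track = null_track()
        assert max_min_statistic(track, window=1) == track.z.max()

    def test_isolated_spike_suppressed(self):
        track = null_track()
        track.z[:] = 0.0
        track.z[200] = 5.0
        assert max_min_statistic(track, window=3) == 0.0

    def test_three_point_plateau_survives(self):
        track = null_track()
        track.z[:] = 0.0
        track.z[200:203] = 5.0
        assert max_min_statistic(track, window=3) == 5.0

    def test_never_exceeds_plain_maximum(self, rng):
        track = simulate_ou_genome(50.0, [100.0] * 3, 0.05, rng)
        assert max_min_statistic(track, window=3) <= max_min_statistic(track, window=1)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            max_min_statistic(null_track(), window=2)


class TestWindowCounts:
    def test_no_rejections_gives_zero(self):
        track = null_track()
        calls = np.zeros(track.grid.M, dtype=bool)
        assert count_significant_windows(calls, track.grid, 1.0) == 0

    def test_stretch_inside_one_anchored_window(self):
        track = null_track(delta=0.02)
        calls = np.zeros(track.grid.M, dtype=bool)
        calls[5:10] = True                    # 0.10-0.18 cM, inside [0, 0.2)
        assert count_significant_windows(calls, track.grid, 0.20) == 1

    def test_distant_rejections_count_separately(self):
        track = null_track(delta=0.02)
        calls = np.zeros(track.grid.M, dtype=bool)
        calls[int(1.0 / 0.02)] = True         # 1.0 cM
        calls[int(5.0 / 0.02)] = True         # 5.0 cM
        assert count_significant_windows(calls, track.grid, 1.0) == 2

    def test_window_smaller_than_spacing_rejected(self):
        track = null_track(delta=0.5)
        with pytest.raises(ValueError):
            count_significant_windows(np.zeros(track.grid.M, bool), track.grid, 0.1)

    def test_null_rejections_cluster_in_few_windows(self):
        """Family-wise errors on null genomes are short excursions: among
        genomes with any rejection at family-wise 0.05, the modal number
        of 0.20 cM windows containing a significant result is 1 and the
        median is at most 2 (an excursion can straddle one anchored
        window boundary)."""
        from ibdscan.thresholds import analytical_quantile

        z_star = analytical_quantile(0.05, 50.0, 10.0, 10, 0.0002).z_star
        rng = np.random.default_rng(314)
        counts = []
        for _ in range(400):
            track = simulate_ou_genome(50.0, [100.0] * 10, 0.02, rng)
            calls = track.z > z_star
            if calls.any():
                counts.append(
                    count_significant_windows(calls, track.grid, 0.20)
                )
        assert len(counts) >= 5
        assert np.bincount(counts).argmax() == 1
        assert np.median(counts) <= 2
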