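"""Trip segmentation, centered durations, resampling and QC filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gulltrack.trips import (
    SegmentationConfig,
    compute_centered_durations,
    filter_trips,
    resample_track,
    segment_trips,
)

NEST = (0.0, 0.0)


def track(times, dists, has_acc=None):
    """Fixes moving straight east at the given nest distances."""
    n = len(times)
    return pd.DataFrame({
        "bird_id": "g1",
        "fix_id": [f"f{i}" for i in range(n)],
        "t": np.asarray(times, float),
        "x": np.asarray(dists, float),
        "y": 0.0,
        "has_acc": has_acc if has_acc is not None else [True] * n,
    })


class TestResample:
    def test_thin_minute_data_to_five_minutes(self):
        fx = track(np.arange(0, 3000, 60), np.zeros(50))
        out = resample_track(fx, 300)
        assert list(out["t"]) == list(np.arange(0, 3000, 300.0))

    def test_already_at_target_unchanged(self):
        fx = track(np.arange(0, 3000, 300), np.zeros(10))
        out = resample_track(fx, 300)
        assert len(out) == len(fx)

    def test_mixed_stream_never_closer_than_target(self):
        rng = np.random.default_rng(0)
        times = np.cumsum(rng.choice([60.0, 300.0], size=200))
        out = resample_track(track(times, np.zeros(200)), 300)
        assert np.all(np.diff(out["t"]) >= 300 - 1)

    def test_empty_input(self):
        assert len(resample_track(track([], []), 300)) == 0


class TestCenteredDurations:
    def test_uniform_intervals(self):
        cd = compute_centered_durations([0, 300, 600, 900, 1200])
        assert list(cd) == [150, 300, 300, 300, 150]

    def test_mixed_intervals_average(self):
        # backward 300 s, forward 600 s -> centered 450 s
        cd = compute_centered_durations([0, 300, 900])
        assert cd[1] == pytest.approx(450)

    def test_single_fix_rejected(self):
        with pytest.raises(ValueError):
            compute_centered_durations([0.0])

    @given(st.lists(st.floats(1, 3600), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_time_conservation(self, gaps):
        t = np.concatenate([[0.0], np.cumsum(gaps)])
        cd = compute_centered_durations(t)
        assert cd.sum() == pytest.approx(t[-1] - t[0], rel=1e-12)
        assert np.all(cd > 0)


class TestSegmentation:
    def test_never_leaving_colony_yields_no_trips(self):
        fx = track(np.arange(0, 3000, 300), np.full(10, 50.0))
        assert segment_trips(fx, NEST) == []

    def test_single_excursion(self):
        d = [0, 50, 500, 1500, 800, 60, 0]
        fx = track(np.arange(0, 7 * 300, 300), d)
        trips = segment_trips(fx, NEST)
        assert len(trips) == 1
        tr = trips[0]
        # bounded by the last fix inside before and the first inside after
        assert tr.start_t == 300 and tr.end_t == 1500
        assert tr.kept
        assert tr.duration_h == pytest.approx((1500 - 300) / 3600)

    def test_two_excursions_split_by_nest_visit(self):
        d = [0, 500, 800, 40, 30, 600, 900, 0]
        fx = track(np.arange(0, 8 * 300, 300), d)
        trips = segment_trips(fx, NEST)
        assert len(trips) == 2

    def test_unclosed_excursion_flagged_not_kept(self):
        d = [0, 500, 900, 1200]
        fx = track(np.arange(0, 4 * 300, 300), d)
        trips = segment_trips(fx, NEST)
        assert len(trips) == 1
        assert not trips[0].kept
        assert trips[0].qc_flags["truncated"]

    def test_idempotent_on_own_fixes(self):
        d = [0, 50, 500, 1500, 800, 60, 0]
        fx = track(np.arange(0, 7 * 300, 300), d)
        trip = segment_trips(fx, NEST)[0]
        again = segment_trips(trip.fixes, NEST)
        assert len(again) == 1
        assert again[0].start_t == trip.start_t
        assert again[0].end_t == trip.end_t

    def test_missing_nest_rejected(self):
        fx = track([0, 300], [0, 0])
        with pytest.raises(ValueError):
            segment_trips(fx, None)


class TestFilters:
    def _trip(self, times, dists, has_acc=None):
        return segment_trips(track(times, dists, has_acc), NEST)[0]

    def test_long_gap_drops_trip(self):
        # 25-minute hole while away from the colony
        t = [0, 300, 600, 600 + 1500, 600 + 1800, 600 + 2100]
        d = [0, 500, 800, 900, 500, 0]
        trip = self._trip(t, d)
        kept, dropped = filter_trips([trip])
        assert not kept
        assert dropped[0][1] == "gap_exceeded"

    def test_low_acc_coverage_drops_trip(self):
        t = np.arange(0, 8 * 300, 300)
        d = [0, 500, 800, 900, 700, 600, 500, 0]
        acc = [True, True, False, False, True, True, True, True]  # 6/8 = 75%
        trip = self._trip(t, d, acc)
        kept, dropped = filter_trips([trip])
        assert not kept
        assert "low_acc_coverage" in dropped[0][1]

    def test_gap_of_exactly_twenty_minutes_kept(self):
        t = [0, 300, 600, 600 + 1200, 2100, 2400]
        d = [0, 500, 800, 900, 500, 0]
        trip = self._trip(t, d)
        kept, _ = filter_trips([trip])
        assert kept

    def test_coverage_of_exactly_eighty_percent_kept(self):
        t = np.arange(0, 10 * 300, 300)
        d = [0, 500, 700, 800, 900, 700, 600, 500, 400, 0]
        acc = [True] * 8 + [False] * 2
        trip = self._trip(t, d, acc)
        kept, _ = filter_trips([trip])
        assert kept

    def test_kept_trip_count_matches_generator(self, gull_days, sim_config):
        fixes, truth = gull_days["fixes"], gull_days["truth"]
        total = 0
        for _, bf in fixes.groupby("bird_id"):
            trips = segment_trips(bf, sim_config.nest_xy)
            kept, _ = filter_trips(trips)
            total += len(kept)
        assert total == len(truth.trips)
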