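"""Behavior detectors against brute-force oracles, and the zoom cutoff."""

import math

import numpy as np
import pytest

from gazemap.roi_extraction import (
    Behavior,
    BehaviorConfig,
    ViewingROI,
    detect_fixations,
    detect_slow_pannings,
    detect_zoom_peaks,
    extract_viewing_rois,
    read_roi_csv,
    write_roi_csv,
)
from gazemap.viewport_log import Interpretation, ViewportRecord, assign_durations


def _records(zooms, centers=None, dwells=None):
    n = len(zooms)
    centers = centers or [(50 + 10 * i, 50) for i in range(n)]
    dwells = dwells or [1.0] * n
    ts = np.concatenate([[0.0], np.cumsum(dwells)[:-1]])
    recs = [
        ViewportRecord(x=int(cx - 20), y=int(cy - 20), width=40, height=40,
                       zoom=float(z), timestamp=float(t))
        for z, (cx, cy), t in zip(zooms, centers, ts)
    ]
    return assign_durations(recs)


class TestZoomPeaks:
    def test_strict_local_maximum(self):
        assert detect_zoom_peaks(_records([2, 10, 5])) == [1]

    def test_flat_sequence_has_no_peak(self):
        assert detect_zoom_peaks(_records([2, 2, 2])) == []

    def test_endpoints_never_flagged(self):
        assert detect_zoom_peaks(_records([10, 2, 10])) == []

    def test_matches_bruteforce_on_random_sequences(self, rng):
        for _ in range(100):
            zooms = rng.choice([1.0, 2.0, 4.0, 8.0, 16.0], size=rng.integers(1, 15))
            recs = _records(zooms)
            oracle = [
                i for i in range(1, len(recs) - 1)
                if zooms[i] > zooms[i - 1] and zooms[i] > zooms[i + 1]
            ]
            assert detect_zoom_peaks(recs) == oracle


class TestSlowPannings:
    def test_small_move_at_constant_zoom(self):
        recs = _records([8, 8], centers=[(100, 100), (150, 100)])
        assert detect_slow_pannings(recs) == [1]

    def test_large_move_not_flagged(self):
        recs = _records([8, 8], centers=[(100, 100), (250, 100)])
        assert detect_slow_pannings(recs) == []

    def test_zoom_change_not_flagged(self):
        recs = _records([8, 9], centers=[(100, 100), (110, 100)])
        assert detect_slow_pannings(recs) == []

    def test_matches_bruteforce_on_random_walks(self, rng):
        config = BehaviorConfig()
        for _ in range(50):
            n = 40
            zooms = rng.choice([4.0, 8.0], size=n)
            centers = np.cumsum(rng.uniform(-80, 80, size=(n, 2)), axis=0) + 500
            recs = _records(zooms, centers=[tuple(c) for c in centers])
            oracle = []
            for i in range(1, n):
                (ax, ay), (bx, by) = recs[i - 1].center, recs[i].center
                if zooms[i] == zooms[i - 1] and math.hypot(bx - ax, by - ay) < 100:
                    oracle.append(i)
            assert detect_slow_pannings(recs, config) == oracle


class TestFixations:
    def test_dwell_above_two_seconds(self):
        recs = _records([8, 8, 8], dwells=[1.0, 3.0, 99.0])  # last duration is 0
        assert detect_fixations(recs) == [1]

    def test_over_a_minute_excluded(self):
        recs = _records([8, 8], dwells=[65.0, 1.0])
        assert detect_fixations(recs) == []

    def test_exactly_at_bounds(self):
        config = BehaviorConfig()
        recs = _records([8, 8, 8], dwells=[2.0, 60.0, 1.0])
        # 2 s is not "longer than 2 s"; 60 s is not excluded (strictly over 1 min is)
        assert detect_fixations(recs, config) == [1]

    def test_matches_bruteforce_on_random_durations(self, rng):
        for _ in range(100):
            dwells = rng.uniform(0, 90, size=rng.integers(1, 20)).tolist()
            recs = _records([8.0] * len(dwells), dwells=dwells)
            oracle = [i for i, r in enumerate(recs) if 2.0 < r.duration <= 60.0]
            assert detect_fixations(recs) == oracle


class TestExtractViewingRois:
    def test_low_zoom_session_yields_nothing(self):
        recs = _records([4, 4, 4], dwells=[5.0, 5.0, 5.0])
        interp = Interpretation("c", "p", recs)
        assert extract_viewing_rois(interp) == []

    def test_empty_interpretation(self):
        assert extract_viewing_rois(Interpretation("c", "p", [])) == []

    def test_multiply_flagged_entry_yields_one_roi_per_behavior(self):
        # entry 1: same zoom as entry 0, tiny move, long dwell -> panning + fixation
        recs = _records([8, 8, 8], centers=[(100, 100), (110, 100), (400, 100)],
                        dwells=[1.0, 5.0, 1.0])
        rois = extract_viewing_rois(Interpretation("c", "p", recs))
        tags = {(r.source_index, r.behavior) for r in rois}
        assert (1, Behavior.slow_panning) in tags and (1, Behavior.fixation) in tags

    def test_equals_union_of_detector_oracles_on_simulated_sessions(
        self, small_case, clean_profile
    ):
        from gazemap.synthetic_data import plan_session

        config = BehaviorConfig()
        for seed in range(5):
            interp = plan_session(small_case, clean_profile, seed=seed).interpretation
            recs = interp.records
            expect = set()
            for i in detect_zoom_peaks(recs):
                expect.add((i, Behavior.zoom_peak))
            for i in detect_slow_pannings(recs, config):
                expect.add((i, Behavior.slow_panning))
            for i in detect_fixations(recs, config):
                expect.add((i, Behavior.fixation))
            expect = {(i, b) for i, b in expect if recs[i].zoom > 5.0}
            got = {(r.source_index, r.behavior) for r in extract_viewing_rois(interp)}
            assert got == expect

    def test_roi_rect_is_the_flagged_viewport_clipped_to_frame(self):
        recs = _records([8, 8], centers=[(5, 5), (10, 10)], dwells=[4.0, 1.0])
        rois = extract_viewing_rois(Interpretation("c", "p", recs), frame=(200, 200))
        for r in rois:
            rec = recs[r.source_index]
            x, y, w, h = r.rect
            assert x >= 0 and y >= 0 and x + w <= 200 and y + h <= 200
            assert x >= rec.x and y >= rec.y
            assert x + w <= rec.x + rec.width and y + h <= rec.y + rec.height

    def test_relaxing_thresholds_never_removes_detections(self, small_case, clean_profile):
        from gazemap.synthetic_data import plan_session

        interp = plan_session(small_case, clean_profile, seed=3).interpretation
        tight = BehaviorConfig(panning_max_displacement=50, fixation_min_s=4)
        loose = BehaviorConfig(panning_max_displacement=150, fixation_min_s=2.5)
        got_tight = {(r.source_index, r.behavior) for r in extract_viewing_rois(interp, tight)}
        got_loose = {(r.source_index, r.behavior) for r in extract_viewing_rois(interp, loose)}
        assert got_tight <= got_loose


def test_roi_csv_round_trip():
    rois = [
        ViewingROI(rect=(5, 6, 40, 40), behavior=Behavior.fixation, duration=3.5,
                   source_index=2, pathologist_id="p", case_id="c"),
        ViewingROI(rect=(0, 0, 10, 20), behavior=Behavior.zoom_peak, duration=0.25,
                   source_index=7, pathologist_id="q", case_id="c"),
    ]
    assert read_roi_csv(write_roi_csv(rois)) == rois
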