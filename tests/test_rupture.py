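"""Envelope-rupture detection from the marker/reporter ratio, and mitosis."""

import numpy as np
import pytest

from confine_track.segmentation import NucleusObservation
from confine_track.rupture import (
    compute_ratio_series,
    detect_rupture_end,
    detect_rupture_start,
    detect_ruptures,
    normalize_rupture_trace,
    reclassify_mitosis,
)
from confine_track.tracking import Track


def track_from_ratio(ratios, track_id=0, marker=600.0, x=50.0, y=50.0, start=0):
    """Stationary track whose reporter realizes the requested ratio trace."""
    tr = Track(track_id=track_id)
    for k, r in enumerate(ratios):
        f = start + k
        tr.add(
            NucleusObservation(
                frame_index=f,
                label=1,
                centroid_x=x,
                centroid_y=y,
                bbox=(int(x) - 12, int(y) - 8, int(x) + 13, int(y) + 9),
                area=300.0,
                mean_nuclear_marker=marker,
                mean_reporter=marker / r,
                in_constriction=False,
            )
        )
    return tr


class TestRatioSeries:
    def test_constant_channels_constant_ratio(self):
        s = compute_ratio_series(track_from_ratio([1.2] * 6))
        np.testing.assert_allclose(s.ratio, 1.2)
        np.testing.assert_allclose(s.delta, 0.0)

    def test_photobleaching_cancels_in_ratio(self):
        tr = track_from_ratio([1.2] * 6)
        bleached = Track(track_id=1)
        for k, (f, o) in enumerate(sorted(tr.observations.items())):
            factor = 0.98**k
            bleached.add(
                NucleusObservation(
                    frame_index=f,
                    label=o.label,
                    centroid_x=o.centroid_x,
                    centroid_y=o.centroid_y,
                    bbox=o.bbox,
                    area=o.area,
                    mean_nuclear_marker=o.mean_nuclear_marker * factor,
                    mean_reporter=o.mean_reporter * factor,
                    in_constriction=False,
                )
            )
        np.testing.assert_allclose(
            compute_ratio_series(bleached).ratio, compute_ratio_series(tr).ratio
        )

    def test_zero_reporter_frame_skipped_with_warning(self):
        tr = track_from_ratio([1.0, 1.0, 1.0])
        bad = tr.observations[1]
        object.__setattr__(bad, "mean_reporter", 0.0)
        with pytest.warns(UserWarning, match="zero reporter"):
            s = compute_ratio_series(tr)
        assert s.frames == [0, 2]


class TestRuptureStart:
    def test_flat_series_no_events(self):
        s = compute_ratio_series(track_from_ratio([1.0] * 10))
        assert detect_rupture_start(s) == []

    def test_twenty_percent_jump_triggers(self):
        s = compute_ratio_series(track_from_ratio([1.0, 1.0, 1.3, 1.25, 1.1]))
        starts = detect_rupture_start(s)
        assert starts == [(2, "jump")]

    def test_jump_below_threshold_ignored(self):
        s = compute_ratio_series(track_from_ratio([1.0, 1.0, 1.15, 1.15, 1.1]))
        assert detect_rupture_start(s) == []

    def test_sustained_rise_starts_at_run_base(self):
        s = compute_ratio_series(
            track_from_ratio([1.00, 1.03, 1.06, 1.09, 1.12, 1.15, 1.15])
        )
        starts = detect_rupture_start(s)
        assert starts == [(0, "sustained_rise")]

    def test_noise_scale_plateau_breaks_run(self):
        # sub-floor increments never qualify as a rise
        s = compute_ratio_series(
            track_from_ratio([1.0, 1.001, 1.002, 1.003, 1.004, 1.005, 1.006])
        )
        assert detect_rupture_start(s) == []

    def test_jump_inside_rise_merged_into_one_event(self):
        # a jump inside a qualifying rise yields a single event at the
        # earlier (rise-base) frame
        ratios = [1.00, 1.03, 1.40, 1.45, 1.50, 1.55, 1.58]
        s = compute_ratio_series(track_from_ratio(ratios))
        starts = detect_rupture_start(s)
        assert (2, "jump") in starts and starts[0] == (0, "sustained_rise")
        events = detect_ruptures(track_from_ratio(ratios), 10.0)
        assert len(events) == 1
        assert events[0].start_frame == 0


class TestRuptureEnd:
    def test_recovery_to_within_tolerance_closes_event(self):
        s = compute_ratio_series(track_from_ratio([1.0, 1.5, 1.4, 1.3, 1.05, 1.05, 1.0]))
        end = detect_rupture_end(s, start_frame=1, baseline_tol_frac=0.10, delta_zero_tol=0.05)
        assert end == 5  # 1.05 at frame 4 still falls fast; frame 5 is settled

    def test_never_recovering_trace_stays_open(self):
        s = compute_ratio_series(track_from_ratio([1.0, 1.6, 1.6, 1.55, 1.5, 1.5]))
        assert detect_rupture_end(s, start_frame=1) is None

    def test_full_detection_duration(self):
        ratios = [1.0, 1.0, 1.5, 1.35, 1.2, 1.02, 1.0, 1.0]
        events = detect_ruptures(track_from_ratio(ratios), frame_interval_min=10.0)
        assert len(events) == 1
        e = events[0]
        assert (e.start_frame, e.end_frame) == (2, 6)
        assert e.duration_min == pytest.approx(40.0)
        assert e.baseline_ratio == pytest.approx(1.0)
        assert e.trigger == "jump"

    def test_no_start_inside_open_event(self):
        # second surge before recovery is folded into the first event
        ratios = [1.0, 1.5, 1.4, 1.9, 1.7, 1.5, 1.5]
        events = detect_ruptures(track_from_ratio(ratios), frame_interval_min=10.0)
        assert len(events) == 1
        assert events[0].end_frame is None

    def test_two_separate_events_detected(self):
        ratios = [1.0, 1.5, 1.2, 1.02, 1.0, 1.0, 1.6, 1.2, 1.02, 1.0]
        events = detect_ruptures(track_from_ratio(ratios), frame_interval_min=10.0)
        assert [e.start_frame for e in events] == [1, 6]
        assert all(e.end_frame is not None for e in events)


class TestRatioInvariance:
    def test_global_per_frame_rescaling_changes_no_event(self):
        rng = np.random.default_rng(12)
        ratios = [1.0, 1.0, 1.55, 1.4, 1.25, 1.02, 1.0, 1.0, 1.0, 1.0]
        tr = track_from_ratio(ratios)
        factors = rng.uniform(0.5, 1.5, len(ratios))
        scaled = Track(track_id=1)
        for k, (f, o) in enumerate(sorted(tr.observations.items())):
            scaled.add(
                NucleusObservation(
                    frame_index=f,
                    label=o.label,
                    centroid_x=o.centroid_x,
                    centroid_y=o.centroid_y,
                    bbox=o.bbox,
                    area=o.area,
                    mean_nuclear_marker=o.mean_nuclear_marker * factors[k],
                    mean_reporter=o.mean_reporter * factors[k],
                    in_constriction=False,
                )
            )
        ev_a = detect_ruptures(tr, 10.0)
        ev_b = detect_ruptures(scaled, 10.0)
        assert [(e.start_frame, e.end_frame, e.trigger) for e in ev_a] == [
            (e.start_frame, e.end_frame, e.trigger) for e in ev_b
        ]


class TestMitosisReclassification:
    def _parent_and_candidate(self):
        ratios = [1.0, 1.0, 1.0, 2.0]
        parent = track_from_ratio(ratios, track_id=0, x=50.0, y=50.0)
        cand = detect_ruptures(parent, 10.0)
        assert len(cand) == 1 and cand[0].start_frame == 3
        return parent, cand

    def test_new_nearby_track_reclassified_as_mitosis(self):
        parent, cand = self._parent_and_candidate()
        daughter = track_from_ratio([2.0, 1.5, 1.0], track_id=1, x=62.0, y=50.0, start=4)
        ruptures, mitoses = reclassify_mitosis([parent, daughter], cand, vicinity_um=40.0)
        assert ruptures == []
        assert len(mitoses) == 1
        m = mitoses[0]
        assert m.parent_track_id == 0
        assert m.daughter_track_ids == [1]
        assert m.division_frame == 3
        assert parent.daughter_ids == [1]
        assert daughter.parent_id == 0

    def test_no_new_track_keeps_rupture(self):
        parent, cand = self._parent_and_candidate()
        ruptures, mitoses = reclassify_mitosis([parent], cand, vicinity_um=40.0)
        assert len(ruptures) == 1 and mitoses == []

    def test_distant_new_track_keeps_rupture(self):
        parent, cand = self._parent_and_candidate()
        far = track_from_ratio([1.0, 1.0], track_id=1, x=150.0, y=50.0, start=4)
        ruptures, mitoses = reclassify_mitosis([parent, far], cand, vicinity_um=40.0)
        assert len(ruptures) == 1 and mitoses == []


class TestNormalizedTrace:
    def test_range_zero_one_with_unit_peak(self):
        ratios = [1.0, 1.0, 1.6, 1.4, 1.2, 1.02, 1.0]
        tr = track_from_ratio(ratios)
        s = compute_ratio_series(tr)
        events = detect_ruptures(tr, 10.0)
        trace = normalize_rupture_trace(s, events[0])
        assert trace.max() == pytest.approx(1.0)
        assert trace.min() >= 0.0
        # trace spans pre-rupture frame .. end; the 1.6 peak is its 2nd point
        assert np.argmax(trace) == 1
        assert trace[0] == pytest.approx(1.0 / 1.6)
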