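"""Tests for maze geometry, zone labels, and trajectory-derived series."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fiberphot as fp
from fiberphot.behavior import (OUT, BACK, EventTrain, MazeGeometry,
                                PixelCalibration, TrackingTrace, assign_zones,
                                calibrate_and_assign_zones, classify_direction,
                                compute_velocity, detect_bouts,
                                detect_port_approach, linearize_arm)


class TestGeometry:
    def test_epm_arm_length(self, epm):
        assert epm.arm_length == 35.0  # (75 - 5) / 2

    def test_oft_zone_examples(self, oft):
        assert oft.zone_of(30.0, 30.0) == "center"        # arena midpoint
        assert oft.zone_of(5.0, 5.0) == "border"          # outside 42.43 cm square
        assert oft.oft_center_side == pytest.approx(60 / np.sqrt(2))

    def test_oft_linear_center_option(self):
        oft = MazeGeometry("OFT", oft_center_mode="linear")
        assert oft.oft_center_side == 30.0
        assert oft.zone_of(20.0, 20.0) == "center"

    def test_epm_zone_examples(self, epm):
        # 30 cm along the right open arm (x = 40 + 30), on the midline
        assert epm.zone_of(70.0, 37.5) == "open"
        assert epm.zone_of(37.5, 37.5) == "center"
        assert epm.zone_of(37.5, 10.0) == "closed"

    def test_zero_area_rejected(self):
        with pytest.raises(fp.ParameterError):
            MazeGeometry("OFT", size=0.0)

    def test_rtpp_chambers(self):
        maze = MazeGeometry("RTPP")
        assert maze.zone_of(10.0, 30.0) == "stim"
        assert maze.zone_of(50.0, 30.0) == "nonstim"


class TestCalibration:
    def test_corner_calibration_and_zones(self, oft):
        cal = PixelCalibration.from_corners((100, 100), (700, 700), oft)
        x_px = np.array([100.0, 400.0, 700.0])
        y_px = np.array([100.0, 400.0, 700.0])
        track, zones = calibrate_and_assign_zones(x_px, y_px, oft, cal)
        np.testing.assert_allclose(track.x, [0.0, 30.0, 60.0])
        assert list(zones.labels) == ["border", "center", "border"]

    def test_outside_arena_rejected(self, oft):
        cal = PixelCalibration(origin_px=(0, 0), cm_per_px=(1.0, 1.0))
        with pytest.raises(fp.DataError):
            calibrate_and_assign_zones(np.array([80.0]), np.array([10.0]),
                                       oft, cal)

    def test_short_gaps_interpolated_long_gaps_missing(self, oft):
        cal = PixelCalibration(origin_px=(0, 0), cm_per_px=(1.0, 1.0))
        x = np.full(100, 30.0)
        y = np.full(100, 30.0)
        x[10:12] = np.nan   # 0.1 s gap: filled
        x[50:80] = np.nan   # 1.5 s gap: stays missing
        track, zones = calibrate_and_assign_zones(x, y, oft, cal, rate=20.0)
        assert np.isfinite(track.x[10:12]).all()
        assert np.isnan(track.x[60])
        assert zones.labels[60] == "missing"
        assert zones.labels[11] == "center"

    def test_zone_dwell_partitions_frames(self, epm, rng):
        # random points on the maze: every frame gets exactly one label
        n = 500
        lo, hi = epm._band
        x = np.where(rng.random(n) < 0.5, rng.uniform(0, 75, n),
                     rng.uniform(lo, hi, n))
        y = np.where((x >= lo) & (x <= hi), rng.uniform(0, 75, n),
                     rng.uniform(lo, hi, n))
        track = TrackingTrace(x=x, y=y)
        zones = assign_zones(track, epm)
        total = sum(zones.dwell_s(z) for z in epm.zone_names)
        assert total == pytest.approx(n / track.rate)


class TestVelocity:
    def test_stationary(self):
        track = TrackingTrace(x=np.full(50, 3.0), y=np.full(50, 4.0))
        v = compute_velocity(track)
        assert np.all(v.displacement_mm == 0.0)

    def test_straight_line_arithmetic(self):
        track = TrackingTrace(x=np.arange(50.0), y=np.zeros(50))
        v = compute_velocity(track)  # 1 cm/frame
        np.testing.assert_allclose(v.displacement_mm[1:], 10.0)
        np.testing.assert_allclose(v.speed_cm_s[1:], 20.0)
        assert v.displacement_mm[0] == 0.0

    def test_threshold_correspondence(self):
        # 3.75 mm/frame at 20 Hz = 7.5 cm/s
        track = TrackingTrace(x=np.arange(10.0) * 0.375, y=np.zeros(10))
        v = compute_velocity(track)
        np.testing.assert_allclose(v.speed_cm_s[1:], 7.5)

    def test_matches_hypot_loop(self, rng):
        x = rng.uniform(0, 60, 200)
        y = rng.uniform(0, 60, 200)
        v = compute_velocity(TrackingTrace(x=x, y=y))
        for i in range(1, 200):
            expect = np.hypot(x[i] - x[i - 1], y[i] - y[i - 1]) * 10
            assert v.displacement_mm[i] == expect


class TestLinearize:
    def test_bin_count_and_origin(self, epm):
        track = TrackingTrace(x=np.array([40.0, 66.0, 75.0]),
                              y=np.full(3, 37.5))
        ap = linearize_arm(track, epm)
        assert ap.n_bins == 70  # 35 cm / 0.5 cm
        assert ap.pos_cm[0] == 0.0 and ap.bin_index[0] == 0
        assert ap.pos_cm[1] == pytest.approx(26.0)
        assert ap.bin_index[1] == 52
        assert ap.pos_cm[2] == pytest.approx(35.0)
        assert ap.bin_index[2] == 69  # arm end folded into the last bin

    def test_transverse_offset_ignored_and_reflection_invariant(self, epm):
        mid = 37.5
        for dy in (0.0, 1.0, -1.0):
            ap = linearize_arm(TrackingTrace(x=np.array([66.0]),
                                             y=np.array([mid + dy])), epm)
            assert ap.pos_cm[0] == pytest.approx(26.0)

    def test_center_and_closed_frames_flagged(self, epm):
        track = TrackingTrace(x=np.array([37.5, 37.5]), y=np.array([37.5, 5.0]))
        ap = linearize_arm(track, epm)
        assert np.isnan(ap.pos_cm[0]) and ap.bin_index[0] == -1  # center
        assert ap.arm[1] == "closed_bottom" and ap.pos_cm[1] == pytest.approx(30.0)

    def test_requires_epm(self, oft):
        with pytest.raises(fp.ParameterError):
            linearize_arm(TrackingTrace(x=np.zeros(2), y=np.zeros(2)), oft)


def _arm_track(positions, epm, step_ok=True):
    """Track along the right open arm at given linear positions (cm)."""
    x = 40.0 + np.asarray(positions, float)
    y = np.full(len(x), 37.5)
    return TrackingTrace(x=x, y=y)


class TestDirection:
    def test_all_subthreshold_excluded(self, epm):
        track = _arm_track(np.full(30, 10.0), epm)
        ap = linearize_arm(track, epm)
        seg = classify_direction(ap, compute_velocity(track))
        assert not seg.include.any()
        assert seg.segments == []

    def test_monotone_outward_single_segment(self, epm):
        track = _arm_track(np.arange(30) * 0.5, epm)  # 5 mm/frame outward
        ap = linearize_arm(track, epm)
        seg = classify_direction(ap, compute_velocity(track))
        labs = [s[2] for s in seg.segments]
        assert labs == [OUT]
        s0 = seg.segments[0]
        assert (s0[0], s0[1]) == (1, 29)  # frame 0 has zero displacement

    def test_out_pause_return_hand_fixture(self, epm):
        """Out 10 frames at 5 mm/frame, pause 10 frames (sub-threshold),
        back 10 frames; hand-enumerated labels."""
        pos = np.r_[np.arange(10) * 0.5,                     # 0 .. 4.5 out
                    4.5 + np.arange(10) * 0.01,              # creep (pause)
                    4.59 - (np.arange(1, 11) * 0.45)]        # back to 0.09
        track = _arm_track(pos, epm)
        ap = linearize_arm(track, epm)
        seg = classify_direction(ap, compute_velocity(track))
        labs = [s[2] for s in seg.segments]
        assert labs == [OUT, BACK]
        out_seg, back_seg = seg.segments
        assert (out_seg[0], out_seg[1]) == (1, 9)
        assert (back_seg[0], back_seg[1]) == (20, 29)
        assert all(seg.labels[i] is None for i in range(10, 20))

    def test_time_reversal_swaps_labels(self, epm):
        pos = np.r_[np.arange(10) * 0.5, 4.5 + np.arange(10) * 0.01,
                    4.59 - (np.arange(1, 11) * 0.45)]
        fwd_track = _arm_track(pos, epm)
        rev_track = _arm_track(pos[::-1], epm)
        fwd = classify_direction(linearize_arm(fwd_track, epm),
                                 compute_velocity(fwd_track))
        rev = classify_direction(linearize_arm(rev_track, epm),
                                 compute_velocity(rev_track))
        swap = {OUT: BACK, BACK: OUT}
        assert [swap[s[2]] for s in rev.segments] == \
            [s[2] for s in fwd.segments][::-1]

    def test_never_both_labels(self, epm, rng):
        pos = np.clip(np.cumsum(rng.normal(0, 0.6, 200)), 0, 35)
        track = _arm_track(pos, epm)
        seg = classify_direction(linearize_arm(track, epm),
                                 compute_velocity(track))
        for a, b in zip(seg.segments, seg.segments[1:]):
            assert a[1] < b[0] or a[2] != b[2]
            assert a[1] <= b[0]  # no frame in two segments


class TestBouts:
    def test_ten_second_rule_example(self):
        licks = EventTrain(times=np.array([0.0, 1.0, 2.0, 20.0]))
        bouts = detect_bouts(licks)
        assert len(bouts) == 2
        np.testing.assert_allclose(bouts.onsets, [0.0, 20.0])
        np.testing.assert_allclose(bouts.offsets, [2.0, 20.0])
        np.testing.assert_array_equal(bouts.counts, [3, 1])

    def test_single_and_empty(self):
        assert len(detect_bouts(EventTrain(times=np.array([5.0])))) == 1
        assert len(detect_bouts(EventTrain(times=np.empty(0)))) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bout_count_non_increasing_in_gap(self, seed):
        r = np.random.default_rng(seed)
        licks = EventTrain(times=np.sort(r.uniform(0, 300, 40)))
        counts = [len(detect_bouts(licks, g)) for g in (1.0, 5.0, 10.0, 30.0)]
        assert counts == sorted(counts, reverse=True)


class TestPortApproach:
    def test_sitting_at_port_no_onsets(self):
        track = TrackingTrace(x=np.full(50, 30.0), y=np.full(50, 30.0))
        out = detect_port_approach(track, (30.0, 30.0))
        assert len(out) == 0

    def test_straight_run_single_onset(self):
        x = np.linspace(0, 30, 40)
        track = TrackingTrace(x=x, y=x)  # corner toward port at (30, 30)
        out = detect_port_approach(track, (30.0, 30.0))
        assert len(out) == 1
        assert out.times[0] == track.t[0]

    def test_two_scripted_approaches(self):
        # approach, retreat, approach again; hand-computed onset frames 0 and 60
        seg1 = np.linspace(0, 29, 40)
        seg2 = np.linspace(29, 5, 20)
        seg3 = np.linspace(5, 29.5, 30)
        x = np.r_[seg1, seg2, seg3]
        track = TrackingTrace(x=x, y=np.full(len(x), 30.0))
        out = detect_port_approach(track, (30.0, 30.0))
        assert len(out) == 2
        np.testing.assert_allclose(out.times, [track.t[0], track.t[60]])
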