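"""Board frame, zone-entry detection, occupancy and signal maps."""

import numpy as np
import pytest

from fiberflow import (
    BoardFrame,
    DiscZone,
    EdgeZone,
    GeometryError,
    TrackingTable,
    board_transform,
    detect_zone_events,
    presence_map,
    signal_maps,
    total_event_duration,
)
from fiberflow.preprocess import ProcessedChannel

REF = ((0.0, 100.0), (100.0, 100.0))


def make_track(x, y, frame_rate=25.0, ref=REF, frames=None):
    n = len(x)
    return TrackingTable(
        frame=np.arange(n) if frames is None else np.asarray(frames),
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        frame_rate=frame_rate,
        reference_points=ref,
    )


class TestBoardFrame:
    def test_hand_computed_midpoint(self):
        # P1=(0,100), P2=(100,100) in image pixels (y down): the point (50,50)
        # sits 50 px above the bottom edge -> board (0.5, 0.5)
        frame = BoardFrame(*REF)
        np.testing.assert_allclose(frame.to_board([[50.0, 50.0]]), [[0.5, 0.5]], atol=1e-12)

    def test_anchors_map_to_bottom_corners(self):
        frame = BoardFrame(*REF)
        np.testing.assert_allclose(frame.to_board([REF[0]]), [[0.0, 0.0]], atol=1e-12)
        np.testing.assert_allclose(frame.to_board([REF[1]]), [[1.0, 0.0]], atol=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.random((200, 2)) * 80 + 10
        frame = BoardFrame(*REF)
        base = frame.to_board(pts)

        theta = np.deg2rad(30)
        # rotation in image coordinates about P1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        p1 = np.array(REF[0])
        rpts = (pts - p1) @ rot.T + p1
        rp2 = tuple((np.array(REF[1]) - p1) @ rot.T + p1)
        rframe = BoardFrame(tuple(p1), rp2)
        np.testing.assert_allclose(rframe.to_board(rpts), base, atol=1e-9)

    def test_round_trip_from_board(self):
        frame = BoardFrame((120.0, 380.0), (460.0, 420.0))
        pts = np.array([[0.1, 0.2], [0.9, 0.8], [0.5, 0.0]])
        np.testing.assert_allclose(frame.to_board(frame.from_board(pts)), pts, atol=1e-9)

    def test_degenerate_reference_points(self):
        with pytest.raises(GeometryError):
            BoardFrame((10.0, 10.0), (10.0, 10.0))

    def test_outside_points_clamped_and_counted(self):
        track = make_track([50.0, 150.0], [50.0, 50.0])
        _, traj, n_clamped = board_transform(track)
        assert n_clamped == 1
        assert traj.max() <= 1.0


class TestZoneDetection:
    def test_run_of_30_frames_is_one_event(self):
        n = 100
        traj = np.full((n, 2), 0.9)
        traj[20:50] = (0.5, 0.5)  # 30 frames in the hole
        events = detect_zone_events(traj, DiscZone((0.5, 0.5), 0.08), frame_rate=25.0,
                                    min_duration=0.5)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(1.2)
        assert events[0].t_start == pytest.approx(20 / 25.0)

    def test_never_in_zone(self):
        traj = np.full((100, 2), 0.9)
        assert detect_zone_events(traj, DiscZone(), frame_rate=25.0) == []

    def test_single_frame_break_splits_runs(self):
        traj = np.full((20, 2), 0.5)
        traj[10] = (0.9, 0.9)
        events = detect_zone_events(traj, DiscZone(), frame_rate=25.0, min_duration=0.0)
        assert len(events) == 2

    def test_nan_gap_breaks_run(self):
        traj = np.full((20, 2), 0.5)
        traj[10] = np.nan
        events = detect_zone_events(traj, DiscZone(), frame_rate=25.0)
        assert len(events) == 2

    def test_missing_frame_index_breaks_run(self):
        traj = np.full((20, 2), 0.5)
        frames = np.concatenate([np.arange(10), np.arange(12, 22)])
        events = detect_zone_events(traj, DiscZone(), frame_rate=25.0, frames=frames)
        assert len(events) == 2

    def test_edge_band_zone(self):
        traj = np.array([[0.5, 0.05], [0.5, 0.5], [0.02, 0.5], [0.5, 0.95]])
        inside = EdgeZone(width=0.1).contains(traj)
        np.testing.assert_array_equal(inside, [True, False, True, True])

    def test_duration_consistent_with_frame_count(self):
        rng = np.random.default_rng(4)
        traj = rng.random((500, 2))
        zone = DiscZone((0.5, 0.5), 0.3)
        events = detect_zone_events(traj, zone, frame_rate=25.0)
        in_zone_frames = int(zone.contains(traj).sum())
        assert total_event_duration(events) == pytest.approx(in_zone_frames / 25.0)


class TestPresenceMap:
    def test_stationary_mouse_single_bin(self):
        traj = np.tile([[0.51, 0.51]], (3000, 1))
        occ = presence_map(traj, grid_n=8, frame_rate=25.0)
        assert occ.max() == pytest.approx(120.0)
        assert occ.sum() == pytest.approx(120.0)

    def test_occupancy_conservation_random_walk(self):
        rng = np.random.default_rng(7)
        traj = rng.random((3000, 2))
        occ = presence_map(traj, grid_n=32, frame_rate=25.0)
        assert occ.sum() == pytest.approx(120.0)

    def test_gap_frames_do_not_count(self):
        rng = np.random.default_rng(8)
        traj = rng.random((3000, 2))
        traj[::10] = np.nan  # 10% gaps
        occ = presence_map(traj, grid_n=16, frame_rate=25.0)
        assert occ.sum() == pytest.approx(0.9 * 120.0)

    def test_boundary_points_fall_in_exactly_one_bin(self):
        traj = np.array([[1.0, 1.0], [0.0, 0.0]])
        occ = presence_map(traj, grid_n=4, frame_rate=1.0)
        assert occ.sum() == pytest.approx(2.0)
        assert occ[3, 3] == 1.0 and occ[0, 0] == 1.0


def make_channel(z, fs):
    t = np.arange(z.size) / fs
    return ProcessedChannel(role="sensor_465", time=t, raw=z, filtered=z, zscore=z,
                            sampling_rate=fs)


class TestSignalMaps:
    def test_constant_signal_normalizes_to_one_everywhere(self):
        rng = np.random.default_rng(1)
        n_frames, fr, fs = 500, 25.0, 100.0
        traj = rng.random((n_frames, 2))
        track = make_track(*(rng.random((2, n_frames)) * 100), frame_rate=fr)
        z = np.ones(int(n_frames / fr * fs))
        maps = signal_maps(traj, track, make_channel(z, fs), grid_n=8)
        vals = maps.signal_norm[maps.visited & (maps.sample_count > 0)]
        np.testing.assert_allclose(vals, 1.0, atol=1e-12)
        assert np.all(np.isnan(maps.signal_norm[~maps.visited]))

    def test_two_bin_fixture_mean_independent_of_visit_count(self):
        fr = fs = 10.0  # one photometry sample per frame
        # 30 frames in bin A (left half), 30 in bin B (right half)
        traj = np.vstack([np.tile([[0.25, 0.5]], (30, 1)), np.tile([[0.75, 0.5]], (30, 1))])
        track = make_track(np.zeros(60), np.zeros(60), frame_rate=fr)
        z = np.concatenate([np.full(30, 2.0), np.zeros(30)])
        maps = signal_maps(traj, track, make_channel(z, fs), grid_n=2)
        assert maps.signal_norm[1, 0] == pytest.approx(2.0)
        assert maps.signal_norm[1, 1] == pytest.approx(0.0)

    def test_doubling_dwell_time_keeps_norm_doubles_sum(self):
        fr = fs = 10.0
        single = np.tile([[0.1, 0.1]], (40, 1))
        double = np.tile([[0.1, 0.1]], (80, 1))
        z1 = np.full(40, 1.5)
        z2 = np.full(80, 1.5)
        t1 = make_track(np.zeros(40), np.zeros(40), frame_rate=fr)
        t2 = make_track(np.zeros(80), np.zeros(80), frame_rate=fr)
        m1 = signal_maps(single, t1, make_channel(z1, fs), grid_n=4)
        m2 = signal_maps(double, t2, make_channel(z2, fs), grid_n=4)
        assert m2.signal_norm[0, 0] == pytest.approx(m1.signal_norm[0, 0])
        assert m2.signal_sum[0, 0] == pytest.approx(2 * m1.signal_sum[0, 0])
        assert m2.occupancy[0, 0] == pytest.approx(2 * m1.occupancy[0, 0])

    def test_no_temporal_overlap_rejected(self):
        from fiberflow import AlignmentError

        traj = np.tile([[0.5, 0.5]], (10, 1))
        track = make_track(np.zeros(10), np.zeros(10), frame_rate=25.0,
                           frames=np.arange(10))
        z = np.ones(100)
        ch = ProcessedChannel(role="s", time=50.0 + np.arange(100) / 100.0, raw=z,
                              filtered=z, zscore=z, sampling_rate=100.0)
        with pytest.raises(AlignmentError):
            signal_maps(traj, track, ch)
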