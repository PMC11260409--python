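"""Kalman filtering, gating, assignment and event reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from voidspot import synthetic as syn
from voidspot.calibration import CalibrationCurve, PixelScale
from voidspot.instances import iou_bbox, iou_mask
from voidspot.pipeline import track_video
from voidspot.tracking import (
    KalmanState,
    Tracker,
    TrackerParams,
    assign,
    kalman_predict,
    kalman_update,
    mahalanobis_sq,
    report,
    step,
)

from conftest import disc_instance
from reference_eval import brute_force_assignment

PARAMS = TrackerParams()


def state_at(row, col, area, darea=0.0, P=None, params=PARAMS):
    if P is None:
        P = np.eye(4)
    return KalmanState(x=np.array([row, col, area, darea]), P=P, params=params)


class TestKalman:
    def test_static_model_fixed_point_without_noise(self):
        quiet = TrackerParams(
            process_std_pos=0, process_std_area=0, process_std_darea=0, process_darea_rel=0
        )
        s = state_at(10, 20, 100, darea=0, P=np.zeros((4, 4)), params=quiet)
        out = kalman_predict(s)
        np.testing.assert_allclose(out.x, s.x)
        np.testing.assert_allclose(out.P, s.P)

    def test_linear_area_propagation(self):
        s = state_at(10, 20, 100, darea=5)
        out = kalman_predict(s)
        assert out.x[2] == pytest.approx(105)
        assert out.x[0] == pytest.approx(10) and out.x[1] == pytest.approx(20)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        a=arrays(np.float64, (4, 4), elements=st.floats(-2, 2)),
        darea=st.floats(-5, 5),
    )
    def test_covariance_trace_nondecreasing_under_predict(self, a, darea):
        P = a @ a.T + 1e-9 * np.eye(4)  # random PSD
        s = state_at(0, 0, 50, darea, P=P)
        out = kalman_predict(s)
        assert np.trace(out.P) >= np.trace(P) - 1e-9

    def test_update_pulls_state_toward_measurement(self):
        s = state_at(50, 50, 300, P=np.diag([25.0, 25.0, 400.0, 400.0]))
        det = disc_instance((120, 120), (60, 60), 11)
        out = kalman_update(s, det)
        assert 50 < out.x[0] < 60 and 50 < out.x[1] < 60


class TestMahalanobis:
    def test_zero_residual_at_predicted_mean(self):
        s = state_at(30, 40, 314)
        det = disc_instance((100, 100), (30, 40), 10)
        # construct measurement equal to prediction
        s.x[:2] = det.centroid
        s.x[2] = det.area_px
        assert mahalanobis_sq(s, det) == pytest.approx(0.0, abs=1e-9)

    def test_identity_innovation_reduces_to_euclidean(self):
        # zero state covariance + unit measurement noise => S = I
        params = TrackerParams(meas_std_pos=1.0, meas_std_area=1.0)
        det = disc_instance((100, 100), (30, 40), 10)
        s = KalmanState(
            x=np.array([det.centroid[0] - 3, det.centroid[1] - 4, det.area_px, 0.0]),
            P=np.zeros((4, 4)),
            params=params,
        )
        assert mahalanobis_sq(s, det) == pytest.approx(25.0, abs=1e-9)

    def test_matches_dense_solve_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=(4, 4))
            s = KalmanState(
                x=rng.normal(size=4) * 10 + np.array([50, 50, 300, 0]),
                P=a @ a.T,
                params=PARAMS,
            )
            det = disc_instance((200, 200), (rng.uniform(40, 70), rng.uniform(40, 70)), 9)
            H = np.zeros((3, 4))
            H[0, 0] = H[1, 1] = H[2, 2] = 1
            S = H @ s.P @ H.T + s.measurement_cov()
            resid = np.array([det.centroid[0], det.centroid[1], det.area_px]) - H @ s.x
            oracle = resid @ np.linalg.inv(S) @ resid
            assert mahalanobis_sq(s, det) == pytest.approx(oracle, rel=1e-9)


class TestIoU:
    def test_identical_boxes(self):
        assert iou_bbox((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0

    def test_disjoint_boxes(self):
        assert iou_bbox((0, 0, 2, 2), (5, 5, 7, 7)) == 0.0

    def test_pixel_enumeration_oracle(self):
        # [0,2)x[0,2) vs [0,2)x[1,3): intersection 2 px, union 6 px
        assert iou_bbox((0, 0, 2, 2), (0, 1, 2, 3)) == pytest.approx(1 / 3)

    def test_mask_iou_matches_set_arithmetic(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0:4, 0:4] = True
        b[2:6, 2:6] = True
        assert iou_mask(a, b) == pytest.approx(4 / 28)
        assert iou_mask(a, np.zeros((10, 10), bool)) == 0.0


class TestAssign:
    def test_diagonal_cost_prefers_diagonal(self):
        cost = np.full((3, 3), 1.0) - np.eye(3) * 0.9
        matches, ur, uc = assign(cost)
        assert sorted(matches) == [(0, 0), (1, 1), (2, 2)]
        assert ur == [] and uc == []

    def test_single_feasible_pair(self):
        matches, ur, uc = assign(np.array([[0.3]]), np.array([[True]]))
        assert matches == [(0, 0)]

    def test_empty_matrix(self):
        matches, ur, uc = assign(np.zeros((0, 3)))
        assert matches == [] and ur == [] and uc == [0, 1, 2]

    def test_gate_blocks_infeasible_pairs(self):
        cost = np.array([[0.1, 0.9], [0.9, 0.1]])
        gate = np.array([[False, True], [True, False]])
        matches, _, _ = assign(cost, gate)
        assert sorted(matches) == [(0, 1), (1, 0)]

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        n=st.integers(1, 6),
        m=st.integers(1, 6),
        seed=st.integers(0, 2**20),
        gate_p=st.floats(0.3, 1.0),
    )
    def test_equals_brute_force_over_permutations(self, n, m, seed, gate_p):
        rng = np.random.default_rng(seed)
        cost = rng.uniform(0, 1, (n, m))
        gate = rng.uniform(0, 1, (n, m)) < gate_p
        matches, _, _ = assign(cost, gate)
        total = sum(cost[i, j] for i, j in matches)
        bf_card, bf_cost = brute_force_assignment(cost, gate)
        assert len(matches) == bf_card
        assert total == pytest.approx(bf_cost, abs=1e-9)


def _video(spots, n_frames=60, noise=0.01, seed=0, shape=(200, 260)):
    cfg = syn.SceneConfig(
        height=shape[0],
        width=shape[1],
        n_frames=n_frames,
        noise_sd=noise,
        rng_seed=seed,
        spots=tuple(spots),
    )
    return syn.render_video(cfg)


class TestStep:
    def test_initialization_spawns_tentative_tracks(self):
        dets = [
            disc_instance((100, 100), (30, 30), 8),
            disc_instance((100, 100), (70, 70), 8),
        ]
        tracks = step([], dets, frame_idx=0)
        assert len(tracks) == 2
        assert all(t.status == "tentative" for t in tracks)
        assert [t.track_id for t in tracks] == [1, 2]

    def test_frame_index_must_increase(self):
        dets = [disc_instance((100, 100), (30, 30), 8)]
        tracks = step([], dets, 5)
        with pytest.raises(ValueError, match="frame index"):
            step(tracks, dets, 5)

    def test_static_single_spot_one_confirmed_track_no_switches(self):
        frames, truth = _video(
            [syn.SpotSpec(center=(100, 130), final_radius=20, growth_timescale=0)],
            n_frames=50,
        )
        tracks = track_video(frames)
        confirmed = [t for t in tracks if t.status == "confirmed"]
        assert len(confirmed) == 1
        assert len(tracks) == 1
        # the track covers the same truth spot in every frame
        for frame, inst in confirmed[0].history:
            assert iou_mask(inst.mask, truth.spots[0].masks[frame]) > 0.5

    def test_staggered_appearances_recover_first_frames(self):
        frames, _ = _video(
            [
                syn.SpotSpec(center=(50, 60), final_radius=18, appearance_frame=10, growth_timescale=5),
                syn.SpotSpec(center=(120, 130), final_radius=16, appearance_frame=40, growth_timescale=5),
                syn.SpotSpec(center=(160, 220), final_radius=15, appearance_frame=80, growth_timescale=5),
            ],
            n_frames=110,
        )
        tracks = track_video(frames)
        confirmed = sorted(
            (t for t in tracks if t.status == "confirmed"), key=lambda t: t.first_frame
        )
        assert len(confirmed) == 3
        assert [t.first_frame for t in confirmed] == [10, 40, 80]

    def test_growing_spot_keeps_single_identity(self):
        frames, _ = _video(
            [syn.SpotSpec(center=(100, 130), final_radius=24, growth_timescale=12)],
            n_frames=80,
        )
        tracks = track_video(frames)
        assert len(tracks) == 1
        assert tracks[0].status == "confirmed"


class TestReport:
    CURVE = CalibrationCurve(slope=2.0, intercept=0.0, r_squared=1.0)
    SCALE = PixelScale(cm_per_px=0.02)

    def _tracks(self, first_frames, n_frames=100):
        tracker = Tracker(TrackerParams(n_init=1))
        shape = (200, 260)
        centers = [(40 + 50 * i, 40 + 70 * i) for i in range(len(first_frames))]
        for f in range(n_frames):
            dets = [
                disc_instance(shape, c, 12)
                for c, ff in zip(centers, first_frames)
                if f >= ff
            ]
            if dets:
                tracker.step(dets, f)
        return tracker.tracks

    def test_appearance_times_and_intervals(self):
        tracks = self._tracks([10, 40, 80])
        rep = report(tracks, fps=30.0, pixel_scale=self.SCALE, curve=self.CURVE, n_frames=100)
        assert rep.count == 3
        times = [e.appearance_time_s for e in rep.events]
        assert times == pytest.approx([10 / 30, 40 / 30, 80 / 30])
        assert rep.intervals_s == pytest.approx([1.0, 4 / 3])

    def test_empty_session(self):
        rep = report([], fps=30.0, pixel_scale=self.SCALE, curve=self.CURVE, n_frames=100)
        assert rep.count == 0
        assert rep.frequency_per_hour == 0.0
        assert rep.intervals_s == []

    def test_count_equals_confirmed_tracks_and_volume_uses_curve(self):
        tracks = self._tracks([0, 5])
        rep = report(tracks, fps=10.0, pixel_scale=self.SCALE, curve=self.CURVE, n_frames=50)
        confirmed = [t for t in tracks if t.status == "confirmed"]
        assert rep.count == len(confirmed)
        for e in rep.events:
            assert e.volume_ul == pytest.approx(2.0 * e.area_cm2)

    def test_frequency_in_events_per_hour(self):
        tracks = self._tracks([0, 10, 20])
        rep = report(tracks, fps=1.0, pixel_scale=self.SCALE, curve=self.CURVE, n_frames=3600)
        assert rep.frequency_per_hour == pytest.approx(3.0)
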