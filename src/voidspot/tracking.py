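"""Track-by-detection of voiding events across video frames.

Each urine spot is a track: it appears once, stays where it landed, and
spreads by diffusion.  A Kalman filter with state
``(row, col, area, d_area)`` — static position, linearly growing area —
predicts each track between frames; candidate (track, detection) pairs
are gated by the squared Mahalanobis distance of the measurement
``(row, col, area)`` under the predicted innovation covariance, and the
surviving pairs are matched by the Hungarian algorithm on a
``1 - mask IoU`` cost.  Unmatched detections open tentative tracks that
are confirmed after ``n_init`` hits.

Tracks are never deleted: a spot cannot leave the paper, and dropping a
stale track would double-count the spot when it is re-detected.  The
appearance time of each event is the first frame its track was seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .calibration import CalibrationCurve, PixelScale, area_to_volume
from .instances import SpotInstance, iou_bbox, iou_mask  # noqa: F401  (re-exported)

__all__ = [
    "TrackerParams",
    "KalmanState",
    "Track",
    "Tracker",
    "VoidingEvent",
    "EventReport",
    "kalman_predict",
    "kalman_update",
    "mahalanobis_sq",
    "assign",
    "step",
    "report",
    "iou_bbox",
    "iou_mask",
]

# chi-square 0.95 quantile, 3 degrees of freedom (row, col, area measurement)
CHI2_GATE_95_DF3 = 7.814727903251179

_F = np.eye(4)
_F[2, 3] = 1.0  # area grows by d_area per frame
_H = np.zeros((3, 4))
_H[0, 0] = _H[1, 1] = _H[2, 2] = 1.0


@dataclass(frozen=True)
class TrackerParams:
    """Gating, noise and confirmation policy of the tracker."""

    gate_chi2: float = CHI2_GATE_95_DF3
    n_init: int = 3
    process_std_pos: float = 0.5  # px / frame; spots do not move
    process_std_area: float = 10.0  # px^2 / frame, model slack
    process_std_darea: float = 15.0  # px^2 / frame^2, diffusion rate drift
    meas_std_pos: float = 2.0  # px
    meas_std_area: float = 25.0  # px^2
    # area noise grows with the spot: a big spot's area changes by far
    # more pixels per frame than a small one, so the floors above are
    # scaled up relative to the current area estimate
    meas_area_rel: float = 0.05
    process_darea_rel: float = 0.10

    def __post_init__(self) -> None:
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.gate_chi2 <= 0:
            raise ValueError("gate_chi2 must be > 0")


@dataclass
class KalmanState:
    """Gaussian state (row, col, area, d_area) with covariance."""

    x: np.ndarray  # shape (4,)
    P: np.ndarray  # shape (4, 4), symmetric PSD
    params: TrackerParams = field(default_factory=TrackerParams)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).reshape(4)
        self.P = np.asarray(self.P, dtype=float).reshape(4, 4)

    @classmethod
    def from_detection(cls, det: SpotInstance, params: TrackerParams) -> "KalmanState":
        x = np.array([det.centroid[0], det.centroid[1], float(det.area_px), 0.0])
        # wide initial covariance, especially on the unobserved growth rate
        P = np.diag(
            [
                (2 * params.meas_std_pos) ** 2,
                (2 * params.meas_std_pos) ** 2,
                (2 * params.meas_std_area) ** 2,
                (10 * params.meas_std_area) ** 2,
            ]
        ).astype(float)
        return cls(x=x, P=P, params=params)

    def measurement_cov(self) -> np.ndarray:
        p = self.params
        std_area = max(p.meas_std_area, p.meas_area_rel * self.x[2])
        return np.diag([p.meas_std_pos**2, p.meas_std_pos**2, std_area**2])

    def process_cov(self) -> np.ndarray:
        p = self.params
        std_darea = max(p.process_std_darea, p.process_darea_rel * self.x[2])
        return np.diag(
            [
                p.process_std_pos**2,
                p.process_std_pos**2,
                p.process_std_area**2,
                std_darea**2,
            ]
        )


def kalman_predict(state: KalmanState) -> KalmanState:
    """One-step prediction under the static-position / linear-growth model."""
    x = _F @ state.x
    P = _F @ state.P @ _F.T + state.process_cov()
    x[2] = max(x[2], 0.0)  # area cannot go negative
    return KalmanState(x=x, P=P, params=state.params)


def kalman_update(state: KalmanState, det: SpotInstance) -> KalmanState:
    """Standard Kalman measurement update with z = (row, col, area)."""
    z = np.array([det.centroid[0], det.centroid[1], float(det.area_px)])
    S = _H @ state.P @ _H.T + state.measurement_cov()
    K = np.linalg.solve(S.T, (_H @ state.P.T)).T  # P H^T S^-1
    innov = z - _H @ state.x
    x = state.x + K @ innov
    P = (np.eye(4) - K @ _H) @ state.P
    P = (P + P.T) / 2.0  # keep symmetric
    x[2] = max(x[2], 0.0)
    return KalmanState(x=x, P=P, params=state.params)


def mahalanobis_sq(state: KalmanState, det: SpotInstance) -> float:
    """Squared Mahalanobis distance of a detection from the predicted state.

    Uses the innovation covariance ``S = H P H' + R``; if S is singular
    it is regularised by a small multiple of the identity.
    """
    z = np.array([det.centroid[0], det.centroid[1], float(det.area_px)])
    S = _H @ state.P @ _H.T + state.measurement_cov()
    innov = z - _H @ state.x
    try:
        y = np.linalg.solve(S, innov)
    except np.linalg.LinAlgError:
        S = S + 1e-6 * np.trace(S) / 3.0 * np.eye(3) + 1e-12 * np.eye(3)
        y = np.linalg.solve(S, innov)
    return float(innov @ y)


def assign(
    cost: np.ndarray, gate: np.ndarray | None = None
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost one-to-one matching over feasible pairs.

    Maximises the number of feasible matches first, then minimises the
    total cost among them (Hungarian algorithm with big-constant padding
    for pairs the gate marks infeasible).  Costs must be finite and
    small compared to 1e6.

    Returns ``(matches, unmatched_rows, unmatched_cols)``.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        n_rows = cost.shape[0] if cost.ndim == 2 else 0
        n_cols = cost.shape[1] if cost.ndim == 2 else 0
        return [], list(range(n_rows)), list(range(n_cols))
    if gate is None:
        gate = np.ones_like(cost, dtype=bool)
    padded = np.where(gate, cost, 1e9)
    rows, cols = linear_sum_assignment(padded)
    matches = [(int(i), int(j)) for i, j in zip(rows, cols) if gate[i, j]]
    matched_rows = {i for i, _ in matches}
    matched_cols = {j for _, j in matches}
    unmatched_rows = [i for i in range(cost.shape[0]) if i not in matched_rows]
    unmatched_cols = [j for j in range(cost.shape[1]) if j not in matched_cols]
    return matches, unmatched_rows, unmatched_cols


@dataclass
class Track:
    """One voiding event followed through the video."""

    track_id: int
    kalman: KalmanState
    first_frame: int
    hits: int = 1
    status: str = "tentative"
    history: list[tuple[int, SpotInstance]] = field(default_factory=list)

    @property
    def last_frame(self) -> int:
        return self.history[-1][0]

    @property
    def last_instance(self) -> SpotInstance:
        return self.history[-1][1]

    def appearance_time_s(self, fps: float) -> float:
        return self.first_frame / fps


def step(
    tracks: list[Track],
    detections: list[SpotInstance],
    frame_idx: int,
    params: TrackerParams = TrackerParams(),
) -> list[Track]:
    """Advance tracking by one frame.

    Predict every track, gate (track, detection) pairs by Mahalanobis
    distance and non-zero mask overlap, match by Hungarian on
    ``1 - mask IoU``, update matched tracks, and open a tentative track
    per unmatched detection.  Tracks are never deleted.  ``frame_idx``
    must be strictly greater than every frame already in the histories.
    """
    if tracks:
        last = max(t.last_frame for t in tracks)
        if frame_idx <= last:
            raise ValueError(f"frame index {frame_idx} not after last frame {last}")

    for track in tracks:
        track.kalman = kalman_predict(track.kalman)

    n_t, n_d = len(tracks), len(detections)
    if n_t and n_d:
        cost = np.ones((n_t, n_d))
        gate = np.zeros((n_t, n_d), dtype=bool)
        for i, track in enumerate(tracks):
            for j, det in enumerate(detections):
                iou = iou_mask(track.last_instance.mask, det.mask)
                cost[i, j] = 1.0 - iou
                gate[i, j] = iou > 0.0 and mahalanobis_sq(track.kalman, det) <= params.gate_chi2
        matches, _, unmatched_dets = assign(cost, gate)
    else:
        matches, unmatched_dets = [], list(range(n_d))

    for i, j in matches:
        track = tracks[i]
        track.kalman = kalman_update(track.kalman, detections[j])
        track.history.append((frame_idx, detections[j]))
        track.hits += 1
        if track.hits >= params.n_init:
            track.status = "confirmed"

    next_id = max((t.track_id for t in tracks), default=0) + 1
    for j in unmatched_dets:
        det = detections[j]
        track = Track(
            track_id=next_id,
            kalman=KalmanState.from_detection(det, params),
            first_frame=frame_idx,
            history=[(frame_idx, det)],
        )
        if track.hits >= params.n_init:
            track.status = "confirmed"
        tracks.append(track)
        next_id += 1
    return tracks


class Tracker:
    """Stateful convenience wrapper around :func:`step`."""

    def __init__(self, params: TrackerParams = TrackerParams()):
        self.params = params
        self.tracks: list[Track] = []

    def step(self, detections: list[SpotInstance], frame_idx: int) -> list[Track]:
        return step(self.tracks, detections, frame_idx, self.params)

    @property
    def confirmed(self) -> list[Track]:
        return [t for t in self.tracks if t.status == "confirmed"]


@dataclass
class VoidingEvent:
    """Per-event row of the session report."""

    track_id: int
    appearance_frame: int
    appearance_time_s: float
    position: tuple[float, float]  # final centroid (row, col)
    final_area_px: int
    area_cm2: float
    volume_ul: float


@dataclass
class EventReport:
    """Session summary: events, voiding frequency, inter-void intervals."""

    events: list[VoidingEvent]
    count: int
    duration_s: float
    frequency_per_hour: float
    intervals_s: list[float]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "track_id": e.track_id,
                    "appearance_frame": e.appearance_frame,
                    "appearance_time_s": e.appearance_time_s,
                    "row": e.position[0],
                    "col": e.position[1],
                    "final_area_px": e.final_area_px,
                    "area_cm2": e.area_cm2,
                    "volume_ul": e.volume_ul,
                }
                for e in self.events
            ],
            columns=[
                "track_id",
                "appearance_frame",
                "appearance_time_s",
                "row",
                "col",
                "final_area_px",
                "area_cm2",
                "volume_ul",
            ],
        )


def report(
    tracks: list[Track],
    fps: float,
    pixel_scale: PixelScale,
    curve: CalibrationCurve,
    n_frames: int | None = None,
) -> EventReport:
    """Build the per-session voiding report from confirmed tracks.

    Each confirmed track becomes one event with its appearance time
    (first-seen frame / fps), final position, final area and calibrated
    volume.  The session summary holds the event count, voiding
    frequency in events/hour, and the successive differences of the
    sorted appearance times.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    confirmed = sorted(
        (t for t in tracks if t.status == "confirmed"), key=lambda t: t.first_frame
    )
    events = []
    for track in confirmed:
        final = track.last_instance
        area_cm2 = pixel_scale.area_px_to_cm2(final.area_px)
        volume = area_to_volume(final.area_px, pixel_scale, curve)
        events.append(
            VoidingEvent(
                track_id=track.track_id,
                appearance_frame=track.first_frame,
                appearance_time_s=track.appearance_time_s(fps),
                position=final.centroid,
                final_area_px=final.area_px,
                area_cm2=area_cm2,
                volume_ul=volume,
            )
        )

    if n_frames is None:
        n_frames = max((t.last_frame for t in tracks), default=0) + 1
    duration_s = n_frames / fps
    times = sorted(e.appearance_time_s for e in events)
    intervals = [t2 - t1 for t1, t2 in zip(times, times[1:])]
    frequency = len(events) / (duration_s / 3600.0) if duration_s > 0 else 0.0
    return EventReport(
        events=events,
        count=len(events),
        duration_s=duration_s,
        frequency_per_hour=frequency,
        intervals_s=intervals,
    )
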