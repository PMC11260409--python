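"""End-to-end convenience: frames in, voiding-event report out.

Chains the stages in their canonical order — detect bright spots,
split merged blobs by watershed, track spots across frames, convert
final areas to volumes through the standard curve — so callers (and the
command-line interface) need a single entry point.
"""

from __future__ import annotations

import numpy as np

from .calibration import CalibrationCurve, PixelScale
from .detection import DetectorParams, detect_spots
from .instances import SpotInstance
from .overlap_split import SplitParams, split_all
from .tracking import EventReport, Track, TrackerParams, report, step

__all__ = ["detect_and_split", "track_video", "run_session"]


def detect_and_split(
    image: np.ndarray,
    detector_params: DetectorParams = DetectorParams(),
    split_params: SplitParams = SplitParams(),
) -> list[SpotInstance]:
    """Detect spots in one frame and split merged blobs."""
    return split_all(detect_spots(image, detector_params), image, split_params)


def track_video(
    frames: np.ndarray,
    detector_params: DetectorParams = DetectorParams(),
    split_params: SplitParams = SplitParams(),
    tracker_params: TrackerParams = TrackerParams(),
) -> list[Track]:
    """Run detection + splitting + tracking over a frame sequence."""
    tracks: list[Track] = []
    for t, frame in enumerate(np.asarray(frames)):
        detections = detect_and_split(frame, detector_params, split_params)
        step(tracks, detections, t, tracker_params)
    return tracks


def run_session(
    frames: np.ndarray,
    fps: float,
    pixel_scale: PixelScale,
    curve: CalibrationCurve,
    detector_params: DetectorParams = DetectorParams(),
    split_params: SplitParams = SplitParams(),
    tracker_params: TrackerParams = TrackerParams(),
) -> tuple[list[Track], EventReport]:
    """Full session analysis: tracks plus the calibrated event report."""
    frames = np.asarray(frames)
    tracks = track_video(frames, detector_params, split_params, tracker_params)
    rep = report(tracks, fps, pixel_scale, curve, n_frames=frames.shape[0])
    return tracks, rep
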