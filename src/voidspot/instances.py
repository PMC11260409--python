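"""Shared per-spot instance container and overlap measures.

A :class:`SpotInstance` is the unit every pipeline stage exchanges: the
detector emits them, the watershed splitter consumes and re-emits them,
the tracker matches them across frames, and the metrics module scores
them against ground truth.

Conventions used throughout the package:

* coordinates are ``(row, col)``, 0-based;
* bounding boxes are half-open ``(r0, c0, r1, c1)`` with
  ``r0 <= r < r1``, ``c0 <= c < c1``;
* masks are boolean rasters the size of the full frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpotInstance", "iou_bbox", "iou_mask", "bbox_from_mask"]


def bbox_from_mask(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight half-open bounding box ``(r0, c0, r1, c1)`` of a boolean mask."""
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    if not rows.any():
        raise ValueError("cannot compute bounding box of an empty mask")
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return int(r0), int(c0), int(r1) + 1, int(c1) + 1


@dataclass
class SpotInstance:
    """One detected or annotated urine spot.

    Attributes
    ----------
    mask : ndarray of bool
        Frame-sized boolean raster of the spot's pixels.
    bbox : (r0, c0, r1, c1)
        Tight half-open bounding box of ``mask``.
    area_px : int
        Pixel count of ``mask``.
    centroid : (row, col)
        Mean pixel coordinate of the mask.
    score : float
        Detection confidence in [0, 1]; ground-truth instances use 1.0.
    """

    mask: np.ndarray
    bbox: tuple[int, int, int, int] = field(default=None)  # type: ignore[assignment]
    area_px: int = 0
    centroid: tuple[float, float] = (0.0, 0.0)
    score: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D boolean raster")
        area = int(self.mask.sum())
        if area < 1:
            raise ValueError("SpotInstance requires a non-empty mask")
        self.area_px = area
        self.bbox = bbox_from_mask(self.mask)
        rr, cc = np.nonzero(self.mask)
        self.centroid = (float(rr.mean()), float(cc.mean()))
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")

    @classmethod
    def from_mask(cls, mask: np.ndarray, score: float = 1.0) -> "SpotInstance":
        return cls(mask=mask, score=score)


def iou_bbox(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    """Intersection-over-union of two half-open (r0, c0, r1, c1) boxes.

    Returns 0.0 for disjoint boxes and when the union is empty.
    """
    ar0, ac0, ar1, ac1 = a
    br0, bc0, br1, bc1 = b
    ih = min(ar1, br1) - max(ar0, br0)
    iw = min(ac1, bc1) - max(ac0, bc0)
    if ih <= 0 or iw <= 0:
        return 0.0
    inter = ih * iw
    area_a = max(ar1 - ar0, 0) * max(ac1 - ac0, 0)
    area_b = max(br1 - br0, 0) * max(bc1 - bc0, 0)
    union = area_a + area_b - inter
    if union <= 0:
        return 0.0
    return inter / union


def iou_mask(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks; 0.0 on empty union."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(inter) / float(union)
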