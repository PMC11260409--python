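"""Per-image spot detection.

Urine spots under UV light are bright, high-contrast blobs on a dark
background, so the built-in detector is a classical pipeline —
threshold, morphological opening, connected components, size filter —
that fills the same contract as a trained instance-segmentation
network: masks plus confidence scores in, tracking and metrics out.
Mask proposals produced elsewhere (e.g. by a neural detector) can be
loaded from COCO JSON through :func:`load_proposals` instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening

from .instances import SpotInstance

__all__ = ["DetectorParams", "detect_spots", "load_proposals"]

# 8-connectivity for component labelling: diagonal wicking along paper
# fibres keeps one spot one component.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class DetectorParams:
    """Knobs of the classical detector.

    threshold_mode
        ``"fixed"`` uses ``fixed_threshold``; ``"otsu"`` picks the
        threshold from the image histogram.
    min_area_px
        Components smaller than this are discarded (noise specks).
    morph_open_radius
        Radius of the disc structuring element for binary opening;
        0 disables opening.
    """

    threshold_mode: str = "fixed"
    fixed_threshold: float = 0.5
    min_area_px: int = 12
    morph_open_radius: int = 1

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("fixed", "otsu"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 0.0 <= self.fixed_threshold <= 1.0:
            raise ValueError("fixed_threshold must be in [0, 1]")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.morph_open_radius < 0:
            raise ValueError("morph_open_radius must be >= 0")


def detect_spots(image: np.ndarray, params: DetectorParams = DetectorParams()) -> list[SpotInstance]:
    """Detect bright spots in a [0, 1] intensity raster.

    Pipeline: threshold -> binary opening -> 8-connected component
    labelling -> discard components below ``min_area_px``.  Each
    surviving component becomes a :class:`SpotInstance` whose score is
    its mean foreground intensity; instances are returned sorted by
    descending score.  An image with no foreground yields an empty list.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("detect_spots expects a non-empty 2-D intensity raster")

    if params.threshold_mode == "otsu":
        if np.ptp(image) == 0:
            return []
        thresh = float(threshold_otsu(image))
    else:
        thresh = params.fixed_threshold

    binary = image > thresh
    if params.morph_open_radius > 0:
        binary = opening(binary, disk(params.morph_open_radius)).astype(bool)
    if not binary.any():
        return []

    labels, n = ndimage.label(binary, structure=_STRUCTURE_8)
    instances: list[SpotInstance] = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if int(mask.sum()) < params.min_area_px:
            continue
        score = float(np.clip(image[mask].mean(), 0.0, 1.0))
        instances.append(SpotInstance(mask=mask, score=score))
    instances.sort(key=lambda inst: -inst.score)
    return instances


def load_proposals(
    path,
    image_id: int,
    *,
    min_score: float = 0.0,
) -> list[SpotInstance]:
    """Load externally produced mask proposals for one image from COCO JSON.

    Accepts both annotation files and results files (polygon or RLE
    segmentations); a missing ``score`` defaults to 1.0.  ``min_score``
    is a user-set confidence cutoff applied after loading, since
    detector confidence calibrations differ.
    """
    from . import io_formats

    ann_set = io_formats.read_coco(path)
    if image_id not in ann_set.images:
        known = sorted(ann_set.images)
        raise ValueError(f"image_id {image_id} not in file (has {known})")
    out: list[SpotInstance] = []
    for ann in ann_set.annotations:
        if ann.image_id != image_id:
            continue
        score = 1.0 if ann.score is None else float(ann.score)
        if score < min_score:
            continue
        out.append(SpotInstance(mask=ann.mask, score=score))
    out.sort(key=lambda inst: -inst.score)
    return out
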