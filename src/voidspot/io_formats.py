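"""Readers and writers for the pipeline's external formats.

Covers COCO instance-segmentation JSON (the interchange format for
ground truth and mask proposals), LabelMe polygon JSON (the annotation
tool's native output), PNG/JPEG stills and frame directories, and CSV
event reports.

Masks are serialised as uncompressed COCO run-length encoding (RLE,
column-major, runs alternating background/foreground starting with
background), which round-trips losslessly; polygons are accepted on
read and rasterised, which is exact up to the usual one-pixel rim
ambiguity of boundary pixels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import polygon2mask

from .instances import SpotInstance, bbox_from_mask

__all__ = [
    "ImageInfo",
    "Annotation",
    "AnnotationSet",
    "rle_encode",
    "rle_decode",
    "read_coco",
    "write_coco",
    "read_labelme",
    "read_frames",
    "write_frames",
    "write_report",
    "write_scene",
    "truth_to_annotations",
    "instances_to_annotations",
    "to_gray",
]

SPOT_CATEGORY = {"id": 1, "name": "spot", "supercategory": "spot"}

# Rec. 709 luma weights for RGB -> grayscale conversion
LUMA_WEIGHTS = (0.2126, 0.7152, 0.0722)


# ---------------------------------------------------------------------------
# COCO run-length encoding (uncompressed, column-major)
# ---------------------------------------------------------------------------


def rle_encode(mask: np.ndarray) -> dict:
    """Encode a boolean mask as uncompressed COCO RLE.

    Runs are counted down the columns (Fortran order) and alternate
    background/foreground, starting with background.
    """
    mask = np.asarray(mask, dtype=bool)
    flat = mask.flatten(order="F").astype(np.int8)
    if flat.size == 0:
        return {"size": list(mask.shape), "counts": []}
    changes = np.flatnonzero(np.diff(flat)) + 1
    boundaries = np.concatenate([[0], changes, [flat.size]])
    counts = np.diff(boundaries).tolist()
    if flat[0] == 1:  # must start with a (possibly zero-length) background run
        counts = [0] + counts
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    """Decode uncompressed COCO RLE back to a boolean mask."""
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for run in counts:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    if pos != h * w:
        raise ValueError(f"RLE counts sum to {pos}, expected {h * w}")
    return flat.reshape((h, w), order="F")


def _polygon_to_mask(coords_xy: list[float], shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a flat COCO polygon [x1, y1, x2, y2, ...] onto a mask."""
    pts = np.asarray(coords_xy, dtype=float).reshape(-1, 2)
    # polygon2mask wants (row, col) vertex order
    return polygon2mask(shape, pts[:, ::-1])


# ---------------------------------------------------------------------------
# Annotation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageInfo:
    id: int
    file_name: str
    height: int
    width: int


@dataclass
class Annotation:
    """One instance annotation: a mask on one image, optional score."""

    id: int
    image_id: int
    mask: np.ndarray
    score: float | None = None
    category_id: int = 1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return bbox_from_mask(self.mask)


@dataclass
class AnnotationSet:
    """Images + single 'spot' category + instance annotations."""

    images: dict[int, ImageInfo] = field(default_factory=dict)
    annotations: list[Annotation] = field(default_factory=list)

    def validate(self) -> None:
        for ann in self.annotations:
            if ann.image_id not in self.images:
                raise ValueError(
                    f"annotation {ann.id} references missing image_id {ann.image_id}"
                )
            info = self.images[ann.image_id]
            if ann.mask.shape != (info.height, info.width):
                raise ValueError(
                    f"annotation {ann.id} mask shape {ann.mask.shape} does not match "
                    f"image {ann.image_id} ({info.height}, {info.width})"
                )
            if not ann.mask.any():
                raise ValueError(f"annotation {ann.id} has an empty mask")

    def for_image(self, image_id: int) -> list[Annotation]:
        return [a for a in self.annotations if a.image_id == image_id]


def write_coco(ann_set: AnnotationSet, path) -> None:
    """Write an AnnotationSet as COCO instance-segmentation JSON (RLE masks)."""
    ann_set.validate()
    images = [
        {"id": im.id, "file_name": im.file_name, "height": im.height, "width": im.width}
        for im in sorted(ann_set.images.values(), key=lambda im: im.id)
    ]
    annotations = []
    for ann in ann_set.annotations:
        r0, c0, r1, c1 = ann.bbox
        record = {
            "id": ann.id,
            "image_id": ann.image_id,
            "category_id": ann.category_id,
            "segmentation": rle_encode(ann.mask),
            "area": ann.area,
            "bbox": [c0, r0, c1 - c0, r1 - r0],  # COCO x, y, w, h
            "iscrowd": 0,
        }
        if ann.score is not None:
            record["score"] = float(ann.score)
        annotations.append(record)
    payload = {"images": images, "annotations": annotations, "categories": [SPOT_CATEGORY]}
    Path(path).write_text(json.dumps(payload))


def read_coco(path) -> AnnotationSet:
    """Read COCO instance-segmentation JSON (polygon or RLE segmentations).

    Accepts annotation files (``{"images": ..., "annotations": ...}``)
    and results lists (``[{"image_id": ..., "segmentation": ...}, ...]``
    with RLE segmentations, from which image sizes are inferred).
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path} is not valid JSON: {exc}") from exc

    out = AnnotationSet()
    if isinstance(payload, list):
        records = payload
        for rec in records:
            seg = rec.get("segmentation")
            if not isinstance(seg, dict):
                raise ValueError(
                    f"results record {rec.get('id', '?')} needs an RLE segmentation "
                    "(polygon results carry no image size)"
                )
            h, w = seg["size"]
            img_id = rec["image_id"]
            out.images.setdefault(img_id, ImageInfo(img_id, f"image_{img_id}", h, w))
    else:
        records = payload.get("annotations", [])
        for im in payload.get("images", []):
            try:
                out.images[im["id"]] = ImageInfo(
                    im["id"], im.get("file_name", ""), im["height"], im["width"]
                )
            except KeyError as exc:
                raise ValueError(f"image record {im!r} is missing {exc}") from exc

    for rec in records:
        try:
            img = out.images[rec["image_id"]]
            seg = rec["segmentation"]
        except KeyError as exc:
            raise ValueError(f"annotation record {rec.get('id', '?')} is missing/bad {exc}") from exc
        shape = (img.height, img.width)
        if isinstance(seg, dict):
            if not isinstance(seg.get("counts"), list):
                raise ValueError(
                    f"annotation {rec.get('id', '?')}: only uncompressed RLE counts are supported"
                )
            mask = rle_decode(seg)
        elif isinstance(seg, list):
            mask = np.zeros(shape, dtype=bool)
            for poly in seg:
                mask |= _polygon_to_mask(poly, shape)
        else:
            raise ValueError(f"annotation {rec.get('id', '?')} has malformed segmentation")
        if mask.shape != shape:
            raise ValueError(f"annotation {rec.get('id', '?')} mask/image size mismatch")
        out.annotations.append(
            Annotation(
                id=rec.get("id", len(out.annotations) + 1),
                image_id=rec["image_id"],
                mask=mask,
                score=rec.get("score"),
                category_id=rec.get("category_id", 1),
            )
        )
    out.validate()
    return out


def read_labelme(path) -> AnnotationSet:
    """Read a LabelMe JSON file (one image, polygon shapes).

    Non-polygon shapes are skipped with a warning.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        height, width = payload["imageHeight"], payload["imageWidth"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise ValueError(f"{path} is not a LabelMe JSON file: {exc}") from exc

    out = AnnotationSet()
    out.images[1] = ImageInfo(1, payload.get("imagePath", path.stem), height, width)
    for i, shape in enumerate(payload.get("shapes", []), start=1):
        if shape.get("shape_type", "polygon") != "polygon":
            warnings.warn(
                f"skipping non-polygon shape {i} ({shape.get('shape_type')!r}) in {path}",
                stacklevel=2,
            )
            continue
        pts_xy = np.asarray(shape["points"], dtype=float)
        mask = polygon2mask((height, width), pts_xy[:, ::-1])
        if not mask.any():
            warnings.warn(f"skipping degenerate polygon {i} in {path}", stacklevel=2)
            continue
        out.annotations.append(Annotation(id=i, image_id=1, mask=mask))
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Frames and reports
# ---------------------------------------------------------------------------


def to_gray(image: np.ndarray) -> np.ndarray:
    """Intensity raster in [0, 1] from an RGB(A) or grayscale image."""
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        image = image / float(np.iinfo(image.dtype).max)
    if image.ndim == 3:
        image = image[..., :3] @ np.asarray(LUMA_WEIGHTS)
    return np.clip(image.astype(float), 0.0, 1.0)


def read_frames(path, fps: float | None = None) -> tuple[np.ndarray, float | None]:
    """Read a frame sequence as intensity rasters in [0, 1].

    ``path`` may be a single still image or a directory of stills
    (sorted by filename; PNG/JPEG).  Frame rate is not stored in still
    sequences, so it is passed through from the caller's config.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
        )
        if not files:
            raise IOError(f"no readable frames in directory {path}")
        frames = np.stack([to_gray(iio.imread(p)) for p in files])
    elif path.is_file():
        frames = to_gray(iio.imread(path))[np.newaxis]
    else:
        raise IOError(f"no such image or frame directory: {path}")
    return frames, fps


def write_frames(frames: np.ndarray, outdir) -> list[Path]:
    """Write frames as 8-bit PNGs named frame_0000.png, frame_0001.png, ..."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = np.atleast_3d(np.asarray(frames))
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    paths = []
    for t, frame in enumerate(frames):
        p = outdir / f"frame_{t:04d}.png"
        iio.imwrite(p, np.round(np.clip(frame, 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths


def write_report(report, path) -> None:
    """Write an EventReport as CSV (header-only when there are no events)."""
    report.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Bridges from in-memory objects to annotation sets
# ---------------------------------------------------------------------------


def instances_to_annotations(
    instances: list[SpotInstance],
    image_id: int = 1,
    image_name: str = "image_1",
    with_scores: bool = True,
    start_ann_id: int = 1,
) -> AnnotationSet:
    """Wrap detected instances on one image as an AnnotationSet."""
    out = AnnotationSet()
    if instances:
        h, w = instances[0].mask.shape
    else:
        raise ValueError("cannot infer image size from zero instances")
    out.images[image_id] = ImageInfo(image_id, image_name, h, w)
    for k, inst in enumerate(instances):
        out.annotations.append(
            Annotation(
                id=start_ann_id + k,
                image_id=image_id,
                mask=inst.mask,
                score=inst.score if with_scores else None,
            )
        )
    return out


def truth_to_annotations(truth) -> AnnotationSet:
    """Per-frame ground truth of a synthetic scene as an AnnotationSet.

    One COCO image per frame (frame index + 1 as image id), one
    annotation per spot visible in that frame.
    """
    out = AnnotationSet()
    ann_id = 1
    for t in range(truth.n_frames):
        img_id = t + 1
        out.images[img_id] = ImageInfo(
            img_id, f"frame_{t:04d}.png", truth.height, truth.width
        )
        for spot in truth.spots:
            mask = spot.masks[t]
            if mask.any():
                out.annotations.append(Annotation(id=ann_id, image_id=img_id, mask=mask))
                ann_id += 1
    return out


def write_scene(frames: np.ndarray, truth, outdir) -> None:
    """Write a synthetic scene: PNG frames plus COCO ground truth."""
    outdir = Path(outdir)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    write_frames(frames, outdir / "frames")
    write_coco(truth_to_annotations(truth), outdir / "truth_coco.json")
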