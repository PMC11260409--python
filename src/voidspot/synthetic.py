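"""Synthetic UV filter-paper scenes with exact ground truth.

Real void-spot-assay data is a sheet of filter paper photographed (or
filmed) under UV light: bright, near-circular urine spots on a dark
background, sometimes overlapping, growing by diffusion for a few
seconds after each voiding event.  This module fabricates such scenes
with pixel-exact ground truth so detection, splitting, tracking,
calibration and evaluation can all be tested without animal data.

Model
-----
* Each spot is a disc with a narrow smoothstep rim centred on its
  nominal radius, so the half-contrast contour coincides with the truth
  boundary (pixel centres strictly inside the radius).  Overlapping
  spots combine by maximum (wet paper saturates).
* In videos a spot appears at its ``appearance_frame`` and its radius
  follows a saturating exponential
  ``r(t) = final_radius * (1 - exp(-(t - t0 + 1)/tau))``
  (one elapsed frame at appearance, floored at a small visible radius),
  so areas are strictly causal and non-decreasing.
* Noise is additive Gaussian, clipped to [0, 1]; truth masks are
  recorded before noise.
* A one-frame scene is by convention a finished still: spots are drawn
  at their final radius, as in :func:`render_image`.

All randomness flows from ``SceneConfig.rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import AffineTransform, warp

from .instances import SpotInstance

__all__ = [
    "SpotSpec",
    "SceneConfig",
    "SpotTruth",
    "SceneTruth",
    "AugmentParams",
    "render_image",
    "render_video",
    "augment",
    "make_rotation",
    "make_translation",
    "apply_transform",
    "split_dataset",
    "random_session",
]

# Width (px) of the smoothstep rim around each spot's nominal radius.
# Kept narrow so half-contrast thresholding recovers the truth disc.
EDGE_WIDTH_PX = 1.0

# Smallest radius a spot is drawn with once it has appeared: a freshly
# deposited drop is never sub-pixel.
MIN_VISIBLE_RADIUS_PX = 1.5


@dataclass(frozen=True)
class SpotSpec:
    """Parameters of one simulated voiding event."""

    center: tuple[float, float]  # (row, col)
    final_radius: float  # px
    appearance_frame: int = 0
    peak_intensity: float = 0.85
    growth_timescale: float = 8.0  # frames
    true_volume_ul: float | None = None

    def __post_init__(self) -> None:
        if self.final_radius <= 0:
            raise ValueError("final_radius must be > 0")
        if self.appearance_frame < 0:
            raise ValueError("appearance_frame must be >= 0")
        if not 0.0 <= self.peak_intensity <= 1.0:
            raise ValueError("peak_intensity must be in [0, 1]")
        if self.growth_timescale < 0:
            raise ValueError("growth_timescale must be >= 0")

    def radius_at(self, frame: int) -> float:
        """Radius (px) at a video frame index; 0 before appearance."""
        if frame < self.appearance_frame:
            return 0.0
        elapsed = frame - self.appearance_frame + 1
        if self.growth_timescale == 0:
            grown = self.final_radius
        else:
            grown = self.final_radius * (1.0 - math.exp(-elapsed / self.growth_timescale))
        return min(self.final_radius, max(grown, min(MIN_VISIBLE_RADIUS_PX, self.final_radius)))


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, noise and event list of one synthetic scene.

    Defaults mirror the acquisition convention of a 1,280 x 720 video
    camera over the filter paper.
    """

    height: int = 720
    width: int = 1280
    n_frames: int = 1
    background_level: float = 0.08
    noise_sd: float = 0.0
    rng_seed: int = 0
    spots: tuple[SpotSpec, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "spots", tuple(self.spots))
        if self.height < 1 or self.width < 1:
            raise ValueError("scene must be at least 1x1 pixels")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.background_level < 1.0:
            raise ValueError("background_level must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for spot in self.spots:
            r, c = spot.center
            if (
                r + spot.final_radius <= 0
                or r - spot.final_radius >= self.height
                or c + spot.final_radius <= 0
                or c - spot.final_radius >= self.width
            ):
                raise ValueError(f"spot at {spot.center} lies fully outside the frame")
            if spot.appearance_frame >= self.n_frames:
                raise ValueError(
                    f"appearance_frame {spot.appearance_frame} outside scene of "
                    f"{self.n_frames} frame(s)"
                )
            if spot.peak_intensity <= self.background_level:
                raise ValueError("peak_intensity must exceed background_level")


@dataclass
class SpotTruth:
    """Exact per-frame ground truth for one simulated spot."""

    center: tuple[float, float]
    final_radius: float
    appearance_frame: int
    true_volume_ul: float | None
    masks: list[np.ndarray]  # one frame-sized bool raster per frame
    areas: np.ndarray  # pixel count per frame

    @property
    def final_mask(self) -> np.ndarray:
        return self.masks[-1]

    @property
    def final_area_px(self) -> int:
        return int(self.areas[-1])


@dataclass
class SceneTruth:
    """Ground truth of a whole scene: one :class:`SpotTruth` per event."""

    height: int
    width: int
    n_frames: int
    spots: list[SpotTruth] = field(default_factory=list)

    def frame_instances(self, frame: int = -1) -> list[SpotInstance]:
        """Truth spots visible in one frame, as ordinary instances."""
        out = []
        for spot in self.spots:
            mask = spot.masks[frame]
            if mask.any():
                out.append(SpotInstance.from_mask(mask))
        return out


def _disc_field(shape: tuple[int, int], center: tuple[float, float], radius: float):
    """Smoothstep disc profile in [0,1] and its truth mask, on a local window."""
    h, w = shape
    cr, cc = center
    pad = int(math.ceil(radius + EDGE_WIDTH_PX)) + 1
    r0 = max(int(math.floor(cr)) - pad, 0)
    r1 = min(int(math.ceil(cr)) + pad + 1, h)
    c0 = max(int(math.floor(cc)) - pad, 0)
    c1 = min(int(math.ceil(cc)) + pad + 1, w)
    if r0 >= r1 or c0 >= c1:
        return (slice(0, 0), slice(0, 0)), np.zeros((0, 0)), np.zeros((0, 0), bool)
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rr - cr, cc_grid - cc)
    inner = radius - EDGE_WIDTH_PX / 2.0
    outer = radius + EDGE_WIDTH_PX / 2.0
    profile = np.clip((outer - dist) / EDGE_WIDTH_PX, 0.0, 1.0)
    # cosine-smooth the linear ramp for a soft rim
    profile = 0.5 * (1.0 - np.cos(np.pi * profile))
    mask = dist < radius
    return (slice(r0, r1), slice(c0, c1)), profile, mask


def _render_frame(config: SceneConfig, radii: list[float]) -> tuple[np.ndarray, list[np.ndarray]]:
    """Noise-free frame with spots at the given radii, plus truth masks."""
    canvas = np.full((config.height, config.width), config.background_level, dtype=float)
    masks: list[np.ndarray] = []
    for spot, radius in zip(config.spots, radii):
        full_mask = np.zeros((config.height, config.width), dtype=bool)
        if radius > 0:
            window, profile, local_mask = _disc_field(
                (config.height, config.width), spot.center, radius
            )
            field_val = config.background_level + (
                spot.peak_intensity - config.background_level
            ) * profile
            canvas[window] = np.maximum(canvas[window], field_val)
            full_mask[window] = local_mask
        masks.append(full_mask)
    return canvas, masks


def render_image(config: SceneConfig) -> tuple[np.ndarray, SceneTruth]:
    """Render a finished still: every spot at its final radius.

    Returns the intensity raster in [0, 1] and the exact ground truth
    (masks recorded before noise).  Identical config and seed give a
    bit-identical raster.
    """
    radii = [spot.final_radius for spot in config.spots]
    canvas, masks = _render_frame(config, radii)
    rng = np.random.default_rng(config.rng_seed)
    if config.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, config.noise_sd, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)

    truth = SceneTruth(config.height, config.width, n_frames=1)
    for spot, mask in zip(config.spots, masks):
        truth.spots.append(
            SpotTruth(
                center=spot.center,
                final_radius=spot.final_radius,
                appearance_frame=spot.appearance_frame,
                true_volume_ul=spot.true_volume_ul,
                masks=[mask],
                areas=np.array([int(mask.sum())]),
            )
        )
    return canvas, truth


def render_video(config: SceneConfig) -> tuple[np.ndarray, SceneTruth]:
    """Render a frame sequence of appearing, diffusing spots.

    Returns an array of shape ``(n_frames, height, width)`` and the
    per-frame ground truth.  A one-frame scene is a still and equals
    :func:`render_image` on the same config.
    """
    if config.n_frames == 1:
        frame, truth = render_image(config)
        return frame[np.newaxis], truth

    rng = np.random.default_rng(config.rng_seed)
    frames = np.empty((config.n_frames, config.height, config.width), dtype=float)
    per_spot_masks: list[list[np.ndarray]] = [[] for _ in config.spots]
    for t in range(config.n_frames):
        radii = [spot.radius_at(t) for spot in config.spots]
        canvas, masks = _render_frame(config, radii)
        if config.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sd, canvas.shape)
        frames[t] = np.clip(canvas, 0.0, 1.0)
        for store, mask in zip(per_spot_masks, masks):
            store.append(mask)

    truth = SceneTruth(config.height, config.width, config.n_frames)
    for spot, masks in zip(config.spots, per_spot_masks):
        truth.spots.append(
            SpotTruth(
                center=spot.center,
                final_radius=spot.final_radius,
                appearance_frame=spot.appearance_frame,
                true_volume_ul=spot.true_volume_ul,
                masks=masks,
                areas=np.array([int(m.sum()) for m in masks]),
            )
        )
    return frames, truth


# ---------------------------------------------------------------------------
# Image augmentation: three derivatives (translated, rotated, affine) per
# original, the standard trick for enlarging a small annotated training set.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentParams:
    """Sampling ranges for the three derivative transforms."""

    max_translate_frac: float = 0.1  # of each image dimension
    rotate_range_deg: tuple[float, float] = (-25.0, 25.0)
    shear_range_deg: tuple[float, float] = (-8.0, 8.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    order: int = 1  # interpolation order; use 0 for masks


def make_translation(d_row: float, d_col: float) -> AffineTransform:
    """Transform shifting content down by ``d_row`` and right by ``d_col``."""
    # skimage transforms map OUTPUT (x, y) to input; invert the shift
    return AffineTransform(translation=(-d_col, -d_row))


def make_rotation(angle_deg: float, shape: tuple[int, int]) -> AffineTransform:
    """Counter-clockwise rotation of image content about the image centre."""
    h, w = shape[:2]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    shift_to = AffineTransform(translation=(-cx, -cy))
    rot = AffineTransform(rotation=math.radians(angle_deg))
    shift_back = AffineTransform(translation=(cx, cy))
    # inverse map for warp: rotate output coords by -angle about the centre
    return shift_to + rot + shift_back


def apply_transform(image: np.ndarray, tf: AffineTransform, order: int = 1) -> np.ndarray:
    """Warp an image (or, with order=0, a mask) with an inverse-map transform."""
    was_bool = image.dtype == bool
    out = warp(image.astype(float), tf, order=order, preserve_range=True, cval=0.0)
    return out > 0.5 if was_bool else out


def augment(
    image: np.ndarray,
    rng_seed: int,
    params: AugmentParams = AugmentParams(),
) -> list[tuple[np.ndarray, AffineTransform]]:
    """Produce exactly three derivative images: translated, rotated, affine.

    Returns ``[(image, transform), ...]`` so annotation masks can be
    warped with the identical transform (use ``order=0``).  Parameters
    are drawn uniformly from the ranges in ``params``; zero-width ranges
    give identity transforms.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot augment an empty image")
    rng = np.random.default_rng(rng_seed)
    h, w = image.shape[:2]

    max_dr = params.max_translate_frac * h
    max_dc = params.max_translate_frac * w
    t_translate = make_translation(
        rng.uniform(-max_dr, max_dr), rng.uniform(-max_dc, max_dc)
    )

    t_rotate = make_rotation(rng.uniform(*params.rotate_range_deg), (h, w))

    scale = rng.uniform(*params.scale_range)
    shear = math.radians(rng.uniform(*params.shear_range_deg))
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    t_affine = (
        AffineTransform(translation=(-cx, -cy))
        + AffineTransform(scale=(scale, scale), shear=shear)
        + AffineTransform(translation=(cx, cy))
    )

    return [
        (apply_transform(image, tf, order=params.order), tf)
        for tf in (t_translate, t_rotate, t_affine)
    ]


def split_dataset(items: list, ratio: float = 0.9, rng_seed: int = 0) -> tuple[list, list]:
    """Deterministic shuffled train/validation partition.

    ``|train| = round(ratio * n)`` (banker's rounding as in Python's
    built-in ``round``); the two parts are disjoint and exhaustive.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    items = list(items)
    n = len(items)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    order = np.random.default_rng(rng_seed).permutation(n)
    n_train = int(round(ratio * n))
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:]]
    return train, val


def random_session(
    rng_seed: int,
    height: int = 240,
    width: int = 320,
    n_frames: int = 120,
    max_events: int = 6,
    radius_range: tuple[float, float] = (12.0, 22.0),
    growth_range: tuple[float, float] = (4.0, 10.0),
    noise_sd: float = 0.01,
    min_gap_px: float = 10.0,
) -> SceneConfig:
    """A random voiding session: staggered, spatially separated events.

    Events appear in the first two thirds of the recording (so the last
    events still have frames in which to be confirmed) at centres spaced
    far enough apart that spots never merge — the regime of a typical
    assay where the animal moves between voids.
    """
    rng = np.random.default_rng(rng_seed)
    n_events = int(rng.integers(1, max_events + 1))
    spots: list[SpotSpec] = []
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(spots) < n_events and attempts < 500:
        attempts += 1
        r = float(rng.uniform(*radius_range))
        cr = float(rng.uniform(r + 2, height - r - 2))
        cc = float(rng.uniform(r + 2, width - r - 2))
        if any(
            np.hypot(cr - orow, cc - ocol) < r + orad + min_gap_px
            for orow, ocol, orad in placed
        ):
            continue
        placed.append((cr, cc, r))
        spots.append(
            SpotSpec(
                center=(cr, cc),
                final_radius=r,
                appearance_frame=int(rng.integers(0, max(1, (2 * n_frames) // 3))),
                growth_timescale=float(rng.uniform(*growth_range)),
            )
        )
    return SceneConfig(
        height=height,
        width=width,
        n_frames=n_frames,
        noise_sd=noise_sd,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        spots=tuple(spots),
    )


def save_scene(frames: np.ndarray, truth: SceneTruth, outdir) -> None:
    """Write frames as PNG and per-frame truth as COCO JSON under ``outdir``."""
    from . import io_formats  # local import: io_formats imports nothing from here

    io_formats.write_scene(frames, truth, outdir)


def with_seed(config: SceneConfig, seed: int) -> SceneConfig:
    """Copy of a scene config with a different RNG seed."""
    return replace(config, rng_seed=seed)
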