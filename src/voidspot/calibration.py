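"""Volume-vs-area standard curve for the void spot assay.

Known urine volumes pipetted onto filter paper produce spots whose area
grows linearly with volume in the sub-100 µL regime, so an ordinary
least-squares line ``volume = slope * area + intercept`` converts a
measured spot area (cm²) into an estimated voided volume (µL).  The
curve carries its validity ceiling: predictions above it are flagged as
extrapolation rather than rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "PixelScale",
    "fit_calibration",
    "area_to_volume",
    "volume_to_area",
]

DEFAULT_VALID_MAX_VOLUME_UL = 100.0


@dataclass(frozen=True)
class CalibrationPoint:
    """One (dispensed volume µL, measured spot area cm²) pair."""

    volume_ul: float
    area_cm2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.volume_ul) and self.volume_ul > 0):
            raise ValueError(f"volume_ul must be positive and finite, got {self.volume_ul}")
        if not (np.isfinite(self.area_cm2) and self.area_cm2 > 0):
            raise ValueError(f"area_cm2 must be positive and finite, got {self.area_cm2}")


@dataclass(frozen=True)
class PixelScale:
    """Physical size of one pixel; links rasters to the standard curve."""

    cm_per_px: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cm_per_px) and self.cm_per_px > 0):
            raise ValueError("cm_per_px must be positive")

    def area_px_to_cm2(self, area_px: float) -> float:
        return float(area_px) * self.cm_per_px**2

    def area_cm2_to_px(self, area_cm2: float) -> float:
        return float(area_cm2) / self.cm_per_px**2


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted line volume(µL) = slope * area(cm²) + intercept.

    ``valid_max_volume_ul`` is the upper edge of the linear regime;
    conversions beyond it emit an extrapolation warning.
    """

    slope: float
    intercept: float
    r_squared: float
    valid_max_volume_ul: float = DEFAULT_VALID_MAX_VOLUME_UL
    n_points: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def fit_calibration(
    points: list[CalibrationPoint],
    *,
    valid_max_volume_ul: float = DEFAULT_VALID_MAX_VOLUME_UL,
    force_zero_intercept: bool = False,
) -> CalibrationCurve:
    """Ordinary least squares of volume on area.

    Points whose volume exceeds ``valid_max_volume_ul`` fall outside the
    linear regime and are excluded with a warning.  R² is
    ``1 - SS_res / SS_tot`` on the retained points.

    Raises
    ------
    ValueError
        With fewer than 2 usable points, or when all areas coincide
        (the slope is then unidentifiable).
    """
    kept = [p for p in points if p.volume_ul <= valid_max_volume_ul]
    dropped = len(points) - len(kept)
    if dropped:
        warnings.warn(
            f"excluded {dropped} calibration point(s) above the "
            f"{valid_max_volume_ul} µL linear-regime ceiling",
            stacklevel=2,
        )
    if len(kept) < 2:
        raise ValueError("calibration needs at least 2 points within the valid range")

    area = np.array([p.area_cm2 for p in kept], dtype=float)
    vol = np.array([p.volume_ul for p in kept], dtype=float)
    if np.ptp(area) == 0:
        raise ValueError("degenerate fit: all calibration areas are identical")

    if force_zero_intercept:
        slope = float(area @ vol / (area @ area))
        intercept = 0.0
    else:
        design = np.column_stack([area, np.ones_like(area)])
        (slope, intercept), *_ = np.linalg.lstsq(design, vol, rcond=None)
        slope, intercept = float(slope), float(intercept)

    pred = slope * area + intercept
    ss_res = float(np.sum((vol - pred) ** 2))
    ss_tot = float(np.sum((vol - vol.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r_squared = min(max(r_squared, 0.0), 1.0)

    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        valid_max_volume_ul=valid_max_volume_ul,
        n_points=len(kept),
    )


def area_to_volume(area_px: float, scale: PixelScale, curve: CalibrationCurve) -> float:
    """Convert a pixel area to urine volume (µL) through the standard curve.

    Negative predictions (possible for tiny spots with a positive
    intercept fit) are clamped to 0 with a warning; predictions above
    the curve's validity ceiling warn about extrapolation.
    """
    area_cm2 = scale.area_px_to_cm2(area_px)
    volume = curve.slope * area_cm2 + curve.intercept
    if volume < 0:
        warnings.warn(
            f"predicted volume {volume:.3g} µL is negative; clamped to 0", stacklevel=2
        )
        return 0.0
    if volume > curve.valid_max_volume_ul:
        warnings.warn(
            f"predicted volume {volume:.3g} µL exceeds the "
            f"{curve.valid_max_volume_ul} µL linear range (extrapolation)",
            stacklevel=2,
        )
    return float(volume)


def volume_to_area(volume_ul: float, curve: CalibrationCurve) -> float:
    """Exact inverse of the linear map: expected spot area (cm²) for a volume.

    Used by the synthetic scene generator to size spots from true
    volumes.  Volumes above the validity ceiling warn (extrapolation).
    """
    if volume_ul > curve.valid_max_volume_ul:
        warnings.warn(
            f"volume {volume_ul:.3g} µL is above the "
            f"{curve.valid_max_volume_ul} µL linear range (extrapolation)",
            stacklevel=2,
        )
    if curve.slope == 0:
        raise ValueError("curve slope is zero; area is undefined")
    return float((volume_ul - curve.intercept) / curve.slope)
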