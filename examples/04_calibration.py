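"""Fit the volume-vs-area standard curve and convert a spot to volume.

Known volumes pipetted onto filter paper give (volume, area) pairs; an
ordinary least-squares line below the 100 µL linear-regime ceiling
converts any measured spot area to an estimated voided volume.
"""

import numpy as np

from voidspot.calibration import (
    CalibrationPoint,
    PixelScale,
    area_to_volume,
    fit_calibration,
)

rng = np.random.default_rng(0)
areas = np.linspace(0.5, 7.5, 8)  # cm²
true_slope = 1.8  # µL per cm²
points = [
    CalibrationPoint(volume_ul=true_slope * a + rng.normal(0, 0.12), area_cm2=a)
    for a in areas
]

curve = fit_calibration(points)
print(f"fitted: volume = {curve.slope:.3f} * area + {curve.intercept:.3f}  "
      f"(R² = {curve.r_squared:.4f}, n = {curve.n_points})")

scale = PixelScale(cm_per_px=0.02)  # 0.02 cm/px -> 1 px = 4e-4 cm²
area_px = 3000
volume = area_to_volume(area_px, scale, curve)
print(f"a detected spot of {area_px} px ({scale.area_px_to_cm2(area_px):.2f} cm²) "
      f"-> {volume:.2f} µL")
# R² near 1 reproduces the tight linear regime expected below 100 µL.
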