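"""Shared fixtures: rasterized discs and small synthetic scenes."""

from __future__ import annotations

import numpy as np
import pytest

from voidspot.instances import SpotInstance


def disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disc: pixel centres strictly inside the radius."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) < radius


def disc_instance(shape, center, radius, score=1.0) -> SpotInstance:
    return SpotInstance(mask=disc_mask(shape, center, radius), score=score)


@pytest.fixture
def shape100():
    return (100, 100)


def random_instances(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    r_range: tuple[float, float] = (4.0, 15.0),
    with_scores: bool = True,
) -> list[SpotInstance]:
    """Random disc instances with distinct scores (ties have measure zero)."""
    out = []
    h, w = shape
    for _ in range(n):
        r = rng.uniform(*r_range)
        center = (rng.uniform(r, h - r), rng.uniform(r, w - r))
        score = float(rng.uniform(0.05, 1.0)) if with_scores else 1.0
        out.append(disc_instance(shape, center, r, score=score))
    return out
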