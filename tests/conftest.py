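"""Shared fixtures: small synthetic slides built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from wsicascade import SynthSpec, generate
from wsicascade.pyramid_io import MaskRaster, build_pyramid


@pytest.fixture(scope="session")
def small_slide():
    """A 1024-px slide with one ~100-px tumor blob (fast to generate)."""
    spec = SynthSpec(
        width0=1024,
        height0=1024,
        tissue_fraction=0.30,
        n_tumor_blobs=1,
        blob_radius_range=(80, 120),
        seed=42,
    )
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def checker_pyramid():
    """Deterministic 256-px pyramid with a colored square on white."""
    level0 = np.full((256, 256, 3), 255, dtype=np.uint8)
    level0[64:192, 64:192] = (200, 80, 120)
    return build_pyramid(level0, min_side=32)


def make_gt(shape: tuple[int, int], boxes: list[tuple[int, int, int, int]]) -> MaskRaster:
    """Level-0 ground truth with rectangular tumor regions (x0,y0,x1,y1)."""
    data = np.zeros(shape, dtype=np.uint8)
    for x0, y0, x1, y1 in boxes:
        data[y0:y1, x0:x1] = 1
    return MaskRaster(data=data, level_scale=1)
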