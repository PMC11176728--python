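from __future__ import annotations

import numpy as np
import pytest

from pollensize.types import Calibration, GrainMask


@pytest.fixture
def cal_unit() -> Calibration:
    return Calibration(1.0)


@pytest.fixture
def cal_quarter() -> Calibration:
    return Calibration(0.25)


def disk_mask(radius: float, pad: int = 3) -> GrainMask:
    """Rasterized disk mask with pixel centers on the integer lattice."""
    n = 2 * int(np.ceil(radius)) + 2 * pad + 1
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    return GrainMask(pixels=(yy - c) ** 2 + (xx - c) ** 2 <= radius**2)


def rect_mask(height: int, width: int, pad: int = 3) -> GrainMask:
    px = np.zeros((height + 2 * pad, width + 2 * pad), dtype=bool)
    px[pad : pad + height, pad : pad + width] = True
    return GrainMask(pixels=px)


@pytest.fixture
def disk_r30() -> GrainMask:
    return disk_mask(30)
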