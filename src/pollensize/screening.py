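"""Rule-based suitability screening of grain masks.

Only intact grains lying flat in polar view yield valid size measurements.
The original pipeline trains a CNN classifier on labelled suitable/unsuitable
crops; no published rule reproduces that network, so this stage encodes the
visually stated criteria as explicit geometric checks:

* ``touches_border`` — a grain clipped by the field of view is truncated and
  cannot yield a valid width;
* ``low_solidity`` — overlapping, folded or fused grains have area well below
  their convex hull's area;
* ``area_out_of_range`` — objects far outside the plausible birch size range
  are detritus or clumps;
* ``multiple_components`` — a crop holding several disjoint objects is not a
  single grain.

The verdict is replaceable: callers may override it per grain with an
external column (e.g. written by the original classifier) via
:func:`apply_external_verdicts`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.morphology import convex_hull_image

from .errors import InvalidInputError
from .types import Calibration, GrainMask


@dataclass
class ScreenConfig:
    solidity_min: float = 0.90
    area_gate_um2: tuple[float, float] = (150.0, 1500.0)
    allow_border: bool = False


@dataclass
class SuitabilityVerdict:
    suitable: bool
    reasons: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.suitable != (len(self.reasons) == 0):
            raise InvalidInputError("suitable flag must mirror an empty reason set")


def solidity(mask: GrainMask) -> float:
    """Foreground area divided by convex-hull area (1.0 for convex shapes)."""
    if mask.n_foreground < 3:
        return 1.0
    hull = convex_hull_image(mask.pixels)
    return float(mask.n_foreground) / float(np.count_nonzero(hull))


def screen(
    mask: GrainMask,
    cal: Calibration,
    config: ScreenConfig | None = None,
) -> SuitabilityVerdict:
    """Judge whether a grain mask is suitable for size measurement."""
    config = config or ScreenConfig()
    reasons: set[str] = set()
    if not config.allow_border and mask.touches_border():
        reasons.add("touches_border")
    if mask.n_components > 1:
        reasons.add("multiple_components")
    if solidity(mask) < config.solidity_min:
        reasons.add("low_solidity")
    lo, hi = config.area_gate_um2
    area = mask.n_foreground * cal.pixel_area_um2
    if not (lo <= area <= hi):
        reasons.add("area_out_of_range")
    return SuitabilityVerdict(suitable=not reasons, reasons=reasons)


def apply_external_verdicts(
    measurements: pd.DataFrame, column: str = "external_suitable"
) -> pd.DataFrame:
    """Override the heuristic ``suitable`` flag with an external verdict column.

    Rows where ``column`` is missing/NaN keep the heuristic verdict; rows
    with a value get that value (truthy/falsy) and an ``external_verdict``
    qc flag appended.
    """
    if column not in measurements.columns:
        return measurements
    out = measurements.copy()
    ext = out[column]
    has = ext.notna()
    out.loc[has, "suitable"] = ext[has].astype(bool)
    if "qc_flags" in out.columns:
        out.loc[has, "qc_flags"] = out.loc[has, "qc_flags"].fillna("").apply(
            lambda s: ";".join(filter(None, [s, "external_verdict"]))
        )
    return out
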