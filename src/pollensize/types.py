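"""Core domain types: calibration, focus stacks, grain masks and measurements.

Geometry convention: rasters are row-major with pixel (0, 0) at the top left
and pixel centers at integer coordinates. A :class:`GrainMask` may be a crop
of a larger source image; ``origin_offset`` locates the crop and
``source_shape`` (when known) the bounds of the source, so border contact can
be judged against the original field of view rather than the crop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration of the microscope image.

    Parameters
    ----------
    microns_per_pixel
        Physical edge length of one pixel in μm. Must be finite and > 0.
    """

    microns_per_pixel: float

    def __post_init__(self) -> None:
        v = float(self.microns_per_pixel)
        if not math.isfinite(v) or v <= 0:
            raise InvalidInputError(
                f"microns_per_pixel must be finite and > 0, got {self.microns_per_pixel!r}"
            )
        object.__setattr__(self, "microns_per_pixel", v)

    @property
    def pixel_area_um2(self) -> float:
        """Area of one pixel in μm²."""
        return self.microns_per_pixel**2


@dataclass
class FocusStack:
    """An ordered stack of co-registered grayscale layers at different focus levels."""

    layers: list[np.ndarray]
    position_id: str = ""

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise InvalidInputError("FocusStack requires at least one layer")
        layers = [np.asarray(layer) for layer in self.layers]
        shape = layers[0].shape
        for i, layer in enumerate(layers):
            if layer.ndim != 2:
                raise InvalidInputError(f"layer {i} is not 2-D (shape {layer.shape})")
            if layer.shape != shape:
                raise InvalidInputError(
                    f"layer {i} shape {layer.shape} differs from layer 0 shape {shape}"
                )
        self.layers = layers

    def __len__(self) -> int:
        return len(self.layers)


@dataclass
class GrainMask:
    """Binary raster of one pollen grain (nonzero = grain).

    Masks produced by :func:`pollensize.imaging.segment_grains` and
    :func:`pollensize.imaging.import_masks` always hold exactly one connected
    foreground component; masks built by hand may hold several, which the
    screening stage flags rather than rejects.
    """

    pixels: np.ndarray
    origin_offset: tuple[int, int] = (0, 0)
    source_id: str = ""
    source_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InvalidInputError(f"mask raster must be 2-D, got shape {px.shape}")
        px = px != 0
        if not px.any():
            raise InvalidInputError("mask has no foreground pixels")
        self.pixels = px
        self.origin_offset = (int(self.origin_offset[0]), int(self.origin_offset[1]))

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())

    @property
    def n_components(self) -> int:
        _, n = ndimage.label(self.pixels)
        return int(n)

    def foreground_coords(self) -> np.ndarray:
        """(N, 2) array of (row, col) coordinates of foreground pixel centers."""
        return np.argwhere(self.pixels)

    def touches_border(self) -> bool:
        """True if the grain touches the border of its source field of view.

        When ``source_shape`` is unknown the crop itself is taken as the field
        of view.
        """
        rows, cols = np.nonzero(self.pixels)
        r0, c0 = self.origin_offset
        if self.source_shape is not None:
            h, w = self.source_shape
        else:
            h, w = self.pixels.shape
            r0 = c0 = 0
        return bool(
            rows.min() + r0 <= 0
            or cols.min() + c0 <= 0
            or rows.max() + r0 >= h - 1
            or cols.max() + c0 >= w - 1
        )


@dataclass
class WidthProfile:
    """Feret widths (μm) sampled over a half-turn of rotation angles.

    ``widths[k]`` is the width at angle ``k * 180 / len(widths)`` degrees; the
    default profile has 180 entries, i.e. one per degree.
    """

    widths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.widths, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise InvalidInputError("width profile must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(w)) or not np.all(w > 0):
            raise InvalidInputError("width profile values must be finite and > 0")
        self.widths = w

    @property
    def thetas_deg(self) -> np.ndarray:
        n = self.widths.size
        return np.arange(n) * (180.0 / n)

    def __len__(self) -> int:
        return self.widths.size


@dataclass
class GrainMeasurement:
    """Per-grain measurement record: calibrated area and rotational mean width."""

    grain_id: str
    sample_id: str
    area_um2: float
    mean_width_um: float
    width_profile: WidthProfile
    suitable: bool = True
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (self.area_um2 > 0):
            raise InvalidInputError("area_um2 must be > 0")
        prof = self.width_profile.widths
        if not np.isclose(self.mean_width_um, prof.mean(), rtol=1e-9, atol=1e-9):
            raise InvalidInputError("mean_width_um must equal the mean of the profile")
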