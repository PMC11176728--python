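"""Image loading, best-focus layer selection and candidate grain masks.

The upstream neural networks that detect and outline pollen in the original
pipeline are deliberately not part of this package. Two routes produce
:class:`~pollensize.types.GrainMask` objects instead:

* :func:`import_masks` ingests binary masks written by any external
  segmentation tool (one file per field of view, any nonzero value is
  foreground, disjoint blobs are split);
* :func:`segment_grains` is a simple classical fallback (global threshold,
  hole filling, border clearing, area gate) that makes the pipeline
  end-to-end runnable on synthetic scenes and clean real images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import clear_border

from .errors import InvalidInputError, MaskFormatError
from .types import Calibration, FocusStack, GrainMask

logger = logging.getLogger(__name__)

_CONTRAST_METRICS = ("laplacian_variance", "intensity_variance")


@dataclass
class SegmentConfig:
    """Configuration for the fallback segmenter.

    ``area_gate_um2`` bounds the calibrated object area; the default
    150–1500 μm² brackets birch pollen generously (reference grains sit
    around 300–480 μm²) while rejecting dust specks and large debris.
    """

    threshold_method: str = "otsu"
    area_gate_um2: tuple[float, float] = (150.0, 1500.0)
    fill_holes: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.area_gate_um2
        if not (0 <= lo < hi):
            raise InvalidInputError(f"invalid area gate {self.area_gate_um2}")
        if self.threshold_method not in ("otsu", "mean"):
            raise InvalidInputError(f"unknown threshold method {self.threshold_method!r}")


def contrast_score(layer: np.ndarray, metric: str = "laplacian_variance") -> float:
    """Focus score of a single layer; larger = sharper."""
    img = np.asarray(layer, dtype=float)
    if metric == "laplacian_variance":
        return float(ndimage.laplace(img).var())
    if metric == "intensity_variance":
        return float(img.var())
    raise InvalidInputError(f"unknown contrast metric {metric!r}; use one of {_CONTRAST_METRICS}")


def select_best_focus(stack: FocusStack, metric: str = "laplacian_variance") -> int:
    """Index of the sharpest layer in a focus stack.

    The score is the variance of a 3×3 Laplacian response by default, a
    standard focus measure that decreases monotonically under Gaussian blur
    and is invariant (as an argmax) under a common affine intensity rescale
    of all layers. Ties resolve to the lowest index.
    """
    scores = [contrast_score(layer, metric) for layer in stack.layers]
    return int(np.argmax(scores))


def read_stack(path: str | Path, position_id: str | None = None) -> FocusStack:
    """Read a (possibly multi-page, possibly jpeg-compressed) TIFF as a FocusStack."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        layers = [arr]
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
        layers = [arr.mean(axis=-1)]
    elif arr.ndim == 3:
        layers = list(arr)
    else:
        raise MaskFormatError(f"cannot interpret {path} with shape {arr.shape} as a stack")
    return FocusStack(layers=layers, position_id=position_id or path.stem)


def segment_grains(
    image: np.ndarray,
    calibration: Calibration,
    config: SegmentConfig | None = None,
) -> list[GrainMask]:
    """Classical fallback segmentation of dark roughly-round objects.

    Global threshold (Otsu by default, objects darker than background),
    hole filling, removal of objects touching the image border, and a
    calibrated area gate. Each returned mask holds exactly one connected
    component, is cropped with a 1-pixel margin, and records its offset and
    the source image shape.
    """
    config = config or SegmentConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise InvalidInputError("segment_grains expects a non-empty 2-D image")
    if img.max() == img.min():
        return []
    if config.threshold_method == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = img.mean()
    fg = img < thr
    if config.fill_holes:
        fg = ndimage.binary_fill_holes(fg)
    fg = clear_border(fg)
    labels = sk_label(fg, connectivity=2)
    lo, hi = config.area_gate_um2
    masks: list[GrainMask] = []
    for region in regionprops(labels):
        area_um2 = region.area * calibration.pixel_area_um2
        if not (lo <= area_um2 <= hi):
            continue
        rs, cs, re, ce = region.bbox
        r0, c0 = max(rs - 1, 0), max(cs - 1, 0)
        r1 = min(re + 1, img.shape[0])
        c1 = min(ce + 1, img.shape[1])
        crop = labels[r0:r1, c0:c1] == region.label
        masks.append(
            GrainMask(
                pixels=crop,
                origin_offset=(r0, c0),
                source_id=f"object{region.label:03d}",
                source_shape=img.shape,
            )
        )
    return masks


def _read_mask_raster(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:
        raise MaskFormatError(f"cannot decode mask file {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] in (2, 3, 4):
        arr = arr.max(axis=-1)
    if arr.ndim != 2:
        raise MaskFormatError(f"mask file {path} is not a 2-D raster (shape {arr.shape})")
    return arr


def import_masks(
    paths: Iterable[str | Path] | str | Path,
    calibration: Calibration | None = None,
) -> list[GrainMask]:
    """Import externally produced binary masks.

    Any nonzero pixel is foreground; rasters holding several disjoint blobs
    are split into one mask per 8-connected component. An all-zero raster
    contributes nothing. ``calibration`` is accepted for interface symmetry
    with :func:`segment_grains` but not needed to build the masks.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    masks: list[GrainMask] = []
    for p in paths:
        path = Path(p)
        raster = _read_mask_raster(path)
        labels, n = ndimage.label(raster != 0, structure=np.ones((3, 3), dtype=int))
        for k in range(1, n + 1):
            comp = labels == k
            rows, cols = np.nonzero(comp)
            r0, r1 = rows.min(), rows.max() + 1
            c0, c1 = cols.min(), cols.max() + 1
            masks.append(
                GrainMask(
                    pixels=comp[r0:r1, c0:c1],
                    origin_offset=(int(r0), int(c0)),
                    source_id=f"{path.stem}#{k}",
                    source_shape=raster.shape,
                )
            )
    return masks


def export_mask(mask: GrainMask, path: str | Path) -> None:
    """Write a mask back to disk in its source frame (PNG or TIFF, 0/255)."""
    path = Path(path)
    shape = mask.source_shape or mask.pixels.shape
    full = np.zeros(shape, dtype=np.uint8)
    r0, c0 = mask.origin_offset
    h, w = mask.pixels.shape
    full[r0 : r0 + h, c0 : c0 + w] = mask.pixels.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, full)
    else:
        Image.fromarray(full).save(path)


def export_masks(masks: Sequence[GrainMask], path: str | Path) -> None:
    """Write several masks of one source image into a single raster file."""
    path = Path(path)
    shapes = {m.source_shape or m.pixels.shape for m in masks}
    if len(shapes) != 1:
        raise InvalidInputError("export_masks requires masks from a single source frame")
    (shape,) = shapes
    full = np.zeros(shape, dtype=np.uint8)
    for m in masks:
        r0, c0 = m.origin_offset
        h, w = m.pixels.shape
        full[r0 : r0 + h, c0 : c0 + w] |= m.pixels.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, full)
    else:
        Image.fromarray(full).save(path)
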