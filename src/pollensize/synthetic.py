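"""Synthetic data generation with analytic ground truth.

Everything the rest of the package consumes can be generated here with known
ground truth and a fixed seed: single triporate-like grain images, composite
slide scenes with detritus / border-clipped / fused grains, per-sample size
datasets drawn from mixtures of normal distributions, and whole synthetic
stratigraphic records.

The grain silhouette is a smooth radial function in polar view,

    r(φ) = base_radius + pore_amplitude · max(0, cos 3(φ − rot))³,

i.e. a disk with three soft protrusions at 120° spacing — the simplest
analytic stand-in for the three pore bulges of a birch grain seen pole-on.
Ground-truth area comes from a supersampled rasterization oracle (and can be
cross-checked against the polar closed form ½∮r(φ)²dφ); ground-truth mean
width comes from projecting the exact analytic boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .errors import InvalidInputError, SceneSizeError
from .sizestats import SampleSeries
from .types import Calibration, GrainMask
from .unmix import MixtureSpec, SpeciesComponent

import pandas as pd

DEFAULT_BACKGROUND = 200.0
DEFAULT_GRAIN_LEVEL = 60.0
DEFAULT_DETRITUS_LEVEL = 100.0


@dataclass(frozen=True)
class GrainShapeSpec:
    """Shape, pose and noise parameters of one synthetic grain."""

    base_radius: float
    pore_amplitude: float = 0.0
    rotation: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.base_radius > 0:
            raise InvalidInputError("base_radius must be > 0")
        if self.pore_amplitude < 0:
            raise InvalidInputError("pore_amplitude must be >= 0")

    @property
    def max_radius(self) -> float:
        return self.base_radius + self.pore_amplitude

    def radius(self, phi: np.ndarray | float) -> np.ndarray | float:
        """Silhouette radius (px) at polar angle ``phi`` (radians)."""
        c = np.cos(3.0 * (np.asarray(phi) - np.deg2rad(self.rotation)))
        return self.base_radius + self.pore_amplitude * np.clip(c, 0.0, None) ** 3


@dataclass
class MixtureSampleSpec:
    """A per-sample size dataset: fixed components, proportions, count, seed."""

    components: list[SpeciesComponent]
    proportions: np.ndarray
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        MixtureSpec(components=self.components, proportions=self.proportions)  # validates
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.n < 1:
            raise InvalidInputError("n must be >= 1")


@dataclass
class SyntheticGrain:
    image: np.ndarray
    mask: GrainMask
    area_um2: float
    mean_width_um: float
    spec: GrainShapeSpec


@dataclass
class Scene:
    image: np.ndarray
    masks: list[GrainMask]
    labels: list[str]


def _inside(spec: GrainShapeSpec, dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
    """Membership test for offsets (rows down, cols right) from the center."""
    rho = np.hypot(dx, dy)
    phi = np.arctan2(-dy, dx)  # y axis points down in raster coordinates
    return rho <= spec.radius(phi)


def silhouette_mask(
    spec: GrainShapeSpec, center: tuple[float, float], shape: tuple[int, int]
) -> np.ndarray:
    """Exact (pixel-center) rasterization of the silhouette on a canvas."""
    cy, cx = center
    rmax = spec.max_radius
    r0 = max(int(np.floor(cy - rmax)) - 1, 0)
    r1 = min(int(np.ceil(cy + rmax)) + 2, shape[0])
    c0 = max(int(np.floor(cx - rmax)) - 1, 0)
    c1 = min(int(np.ceil(cx + rmax)) + 2, shape[1])
    out = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return out
    yy, xx = np.mgrid[r0:r1, c0:c1]
    out[r0:r1, c0:c1] = _inside(spec, yy - cy, xx - cx)
    return out


def silhouette_area_supersampled(
    spec: GrainShapeSpec, cal: Calibration, supersample: int = 10
) -> float:
    """Ground-truth area (μm²) by counting supersampled subpixel centers."""
    rmax = spec.max_radius
    n = int(np.ceil(rmax)) + 2
    step = 1.0 / supersample
    coords = (np.arange(-n * supersample, n * supersample) + 0.5) * step
    dy, dx = np.meshgrid(coords, coords, indexing="ij")
    inside = _inside(spec, dy, dx)
    return float(inside.sum()) * (cal.microns_per_pixel * step) ** 2


def silhouette_area_closed_form(spec: GrainShapeSpec, cal: Calibration) -> float:
    """Ground-truth area (μm²) from the polar closed form ½∮r(φ)²dφ."""
    val, _ = quad(lambda p: float(np.asarray(spec.radius(p)) ** 2), 0.0, 2.0 * np.pi,
                  limit=200)
    return 0.5 * val * cal.pixel_area_um2


def silhouette_mean_width(
    spec: GrainShapeSpec, cal: Calibration, n_angles: int = 360, n_boundary: int = 3600
) -> float:
    """Ground-truth rotational mean width (μm) from the analytic boundary."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_boundary, endpoint=False)
    r = np.asarray(spec.radius(phi))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)
    thetas = np.arange(n_angles) * (np.pi / n_angles)
    proj = pts[:, 0, None] * np.cos(thetas) + pts[:, 1, None] * np.sin(thetas)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.mean()) * cal.microns_per_pixel


def make_grain(
    spec: GrainShapeSpec,
    cal: Calibration,
    background: float = DEFAULT_BACKGROUND,
    grain_level: float = DEFAULT_GRAIN_LEVEL,
    supersample: int = 10,
) -> SyntheticGrain:
    """Render one grain on a small noisy canvas, with ground-truth geometry.

    Deterministic per ``spec.seed``: the same spec yields a bit-identical
    image.
    """
    rmax = spec.max_radius
    half = int(np.ceil(rmax)) + 4
    n = 2 * half + 1
    center = (float(half), float(half))
    fg = silhouette_mask(spec, center, (n, n))
    rng = np.random.default_rng(spec.seed)
    image = np.full((n, n), background, dtype=float)
    image[fg] = grain_level
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)
    mask = GrainMask(pixels=fg, origin_offset=(0, 0), source_id="synthetic",
                     source_shape=(n, n))
    return SyntheticGrain(
        image=image,
        mask=mask,
        area_um2=silhouette_area_supersampled(spec, cal, supersample),
        mean_width_um=silhouette_mean_width(spec, cal),
        spec=spec,
    )


def make_scene(
    grain_specs: list[GrainShapeSpec],
    cal: Calibration,
    detritus_density: float = 0.0,
    overlap_fraction: float = 0.0,
    border_clip: int = 0,
    seed: int = 0,
    canvas_shape: tuple[int, int] = (1200, 1920),
    background: float = DEFAULT_BACKGROUND,
    grain_level: float = DEFAULT_GRAIN_LEVEL,
    noise_sd: float = 6.0,
) -> Scene:
    """Compose grains and detritus on one canvas with ground-truth masks.

    * ``overlap_fraction`` > 0 pairs the grains up and places each pair with
      center distance ``(r₁+r₂)·(1−overlap_fraction)`` so the pair fuses
      into a single object (one mask, labeled ``fused``).
    * ``border_clip`` places that many trailing specs half across the left
      border (labeled ``border_clipped``).
    * ``detritus_density`` is the expected number of irregular dark blobs
      per 10⁶ px².

    Deterministic per ``seed``.
    """
    rng = np.random.default_rng(seed)
    H, W = canvas_shape
    image = np.full((H, W), background, dtype=float)

    if border_clip > len(grain_specs):
        raise InvalidInputError("border_clip exceeds the number of grain specs")
    border_specs = grain_specs[len(grain_specs) - border_clip :]
    interior = grain_specs[: len(grain_specs) - border_clip]

    if overlap_fraction > 0:
        if len(interior) % 2:
            raise InvalidInputError("overlap_fraction > 0 requires an even number of interior grains")
        groups = [interior[i : i + 2] for i in range(0, len(interior), 2)]
    else:
        groups = [[s] for s in interior]

    rmax = max((s.max_radius for s in grain_specs), default=10.0)
    cell = int(2 * np.ceil(rmax) * (2 if overlap_fraction > 0 else 1) + 16)
    ny, nx = (H - 2) // cell, (W - 2) // cell
    if ny * nx < len(groups):
        raise SceneSizeError(
            f"canvas {canvas_shape} fits {ny * nx} cells of {cell} px, need {len(groups)}"
        )
    cells = [(i, j) for i in range(ny) for j in range(nx)]
    order = rng.permutation(len(cells))

    masks: list[GrainMask] = []
    labels: list[str] = []

    def _paint(fg: np.ndarray) -> None:
        image[fg] = grain_level

    for group, ci in zip(groups, order):
        gy, gx = cells[ci]
        cy = gy * cell + cell / 2 + rng.uniform(-3, 3) + 1
        cx = gx * cell + cell / 2 + rng.uniform(-3, 3) + 1
        if len(group) == 1:
            spec = group[0]
            fg = silhouette_mask(spec, (cy, cx), (H, W))
            _paint(fg)
            masks.append(_crop_mask(fg, (H, W), "clean"))
            labels.append("clean")
        else:
            a, b = group
            d = (a.max_radius + b.max_radius) * (1.0 - overlap_fraction)
            ang = rng.uniform(0, 2 * np.pi)
            fa = silhouette_mask(a, (cy - d / 2 * np.sin(ang), cx - d / 2 * np.cos(ang)), (H, W))
            fb = silhouette_mask(b, (cy + d / 2 * np.sin(ang), cx + d / 2 * np.cos(ang)), (H, W))
            fg = fa | fb
            _paint(fg)
            masks.append(_crop_mask(fg, (H, W), "fused"))
            labels.append("fused")

    for i, spec in enumerate(border_specs):
        cy = (i + 1) * H / (len(border_specs) + 1)
        fg = silhouette_mask(spec, (cy, 0.0), (H, W))
        if not fg.any():
            continue
        _paint(fg)
        masks.append(_crop_mask(fg, (H, W), "border_clipped"))
        labels.append("border_clipped")

    n_detritus = int(round(detritus_density * H * W / 1e6))
    for _ in range(n_detritus):
        ry, rx = rng.uniform(2, 9), rng.uniform(2, 9)
        ang = rng.uniform(0, np.pi)
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        half = int(np.ceil(max(ry, rx))) + 2
        y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, H)
        x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, W)
        if y1 <= y0 or x1 <= x0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(ang) + dy * np.sin(ang)
        v = -dx * np.sin(ang) + dy * np.cos(ang)
        blob = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        image[y0:y1, x0:x1][blob] = DEFAULT_DETRITUS_LEVEL

    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=image.shape)
    return Scene(image=np.clip(image, 0, 255).astype(np.uint8), masks=masks, labels=labels)


def _crop_mask(fg: np.ndarray, source_shape: tuple[int, int], source_id: str) -> GrainMask:
    rows, cols = np.nonzero(fg)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    return GrainMask(
        pixels=fg[r0:r1, c0:c1],
        origin_offset=(int(r0), int(c0)),
        source_id=source_id,
        source_shape=source_shape,
    )


def sample_sizes(spec: MixtureSampleSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` sizes from the mixture; returns (values, component labels)."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.components)
    labels = rng.choice(k, size=spec.n, p=spec.proportions)
    mus = np.array([c.mu for c in spec.components])
    sig = np.array([c.sigma for c in spec.components])
    values = rng.normal(mus[labels], sig[labels])
    return values, labels


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def make_stratigraphic_record(
    profile: list[tuple[float, np.ndarray]],
    components: list[SpeciesComponent],
    n_per_sample: int,
    seed: int = 0,
    metric: str = "mean_width",
) -> tuple[list[SampleSeries], pd.DataFrame]:
    """Synthesize one SampleSeries per depth from a proportion profile.

    ``profile`` is a list of ``(depth, proportions)`` pairs in stratigraphic
    order. Returns the series plus a truth table of generating proportions.
    """
    if not profile:
        raise InvalidInputError("profile must be non-empty")
    if n_per_sample < 1:
        raise InvalidInputError("n_per_sample must be >= 1")
    series: list[SampleSeries] = []
    truth_rows = []
    for i, (depth, props) in enumerate(profile):
        mspec = MixtureSampleSpec(
            components=components,
            proportions=np.asarray(props, dtype=float),
            n=n_per_sample,
            seed=_child_seed(seed, i),
        )
        values, _ = sample_sizes(mspec)
        sid = f"S{i:03d}"
        series.append(SampleSeries(sample_id=sid, values=values, metric=metric, depth=depth))
        truth_rows.append(
            {"sample_id": sid, "depth": depth,
             **{f"p_{c.name}": p for c, p in zip(components, mspec.proportions)}}
        )
    return series, pd.DataFrame(truth_rows)


def radius_for_mean_width(width_um: float, cal: Calibration) -> float:
    """Disk base radius (px) whose measured mean width equals ``width_um``.

    Inverts the measurement convention: a disk of radius r px measures
    (2r + 1)·cal μm, so r = (w/cal − 1)/2.
    """
    r = (width_um / cal.microns_per_pixel - 1.0) / 2.0
    if r <= 0:
        raise InvalidInputError(f"width {width_um} μm is below one pixel at this calibration")
    return r


@dataclass
class SceneSample:
    """One synthetic stratigraphic sample rendered as a slide scene."""

    sample_id: str
    depth: float
    image: np.ndarray
    true_widths_um: np.ndarray
    proportions: np.ndarray = field(default_factory=lambda: np.array([]))


def make_stratigraphic_scenes(
    profile: list[tuple[float, np.ndarray]],
    components: list[SpeciesComponent],
    n_per_sample: int,
    cal: Calibration,
    seed: int = 0,
    noise_sd: float = 5.0,
) -> list[SceneSample]:
    """Render a stratigraphic record as microscope-like scenes.

    Widths (μm) are drawn from each depth's mixture and converted to disk
    silhouettes whose measured mean width reproduces the drawn value; each
    sample becomes one scene image sized to hold its grains.
    """
    samples: list[SceneSample] = []
    for i, (depth, props) in enumerate(profile):
        sseed = _child_seed(seed, i)
        mspec = MixtureSampleSpec(
            components=components, proportions=np.asarray(props, dtype=float),
            n=n_per_sample, seed=sseed,
        )
        widths, _ = sample_sizes(mspec)
        specs = [
            GrainShapeSpec(base_radius=radius_for_mean_width(w, cal), seed=sseed + 7 * j + 1)
            for j, w in enumerate(widths)
        ]
        rmax = max(s.max_radius for s in specs)
        cell = int(2 * np.ceil(rmax) + 16)
        ncols = int(np.ceil(np.sqrt(n_per_sample * 1.3)))
        nrows = int(np.ceil(n_per_sample * 1.3 / ncols))
        canvas = (nrows * cell + 4, ncols * cell + 4)
        scene = make_scene(
            specs, cal, seed=sseed, canvas_shape=canvas, noise_sd=noise_sd
        )
        samples.append(
            SceneSample(
                sample_id=f"S{i:03d}",
                depth=depth,
                image=scene.image,
                true_widths_um=widths,
                proportions=mspec.proportions,
            )
        )
    return samples
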