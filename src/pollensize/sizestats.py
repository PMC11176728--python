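"""Per-sample statistical post-processing of grain size series.

Covers the steps between raw per-grain measurements and the unmixing stage:
iterative z-score outlier removal (default |z| > 2.5, two passes with the
mean/SD re-estimated on the survivors between passes), pooling of
consecutive stratigraphic samples into bins (default five 1-cm samples),
summary statistics, and Gaussian kernel density estimates for size-frequency
diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

VALID_METRICS = ("area", "mean_width")


@dataclass
class SampleSeries:
    """Grain sizes of one stratigraphic sample for one chosen metric."""

    sample_id: str
    values: np.ndarray
    metric: str = "mean_width"
    depth: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidInputError("values must be 1-D")
        if v.size and not np.all(v > 0):
            raise InvalidInputError("grain sizes must be > 0")
        if self.metric not in VALID_METRICS:
            raise InvalidInputError(f"metric must be one of {VALID_METRICS}")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class PooledSeries:
    """Concatenation of consecutive samples; ``complete`` is False for a trailing partial bin."""

    member_sample_ids: list[str]
    values: np.ndarray
    metric: str = "mean_width"
    complete: bool = True
    depth: float | None = None  # mean member depth, for plotting/reporting

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def pooled_id(self) -> str:
        return "+".join(self.member_sample_ids)


@dataclass
class SummaryStats:
    mean: float
    sd: float
    n: int
    qc_note: str | None = None


def zscore_filter(
    values: np.ndarray, threshold: float = 2.5, passes: int = 2
) -> np.ndarray:
    """Iteratively drop values with |z| above ``threshold``.

    Each pass recomputes the mean and sample SD (n−1) of the current
    survivors, then removes values whose absolute z-score exceeds the
    threshold. A pass removes nothing when the SD is zero or fewer than
    three values remain. The output is always a subsequence of the input.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("zscore_filter requires a non-empty input")
    for _ in range(passes):
        if v.size < 3:
            break
        sd = v.std(ddof=1)
        if sd == 0:
            break
        z = np.abs(v - v.mean()) / sd
        v = v[z <= threshold]
    return v


def pool(series_list: list[SampleSeries], bin_size: int = 5) -> list[PooledSeries]:
    """Concatenate consecutive non-overlapping groups of ``bin_size`` samples.

    Input must already be in stratigraphic (depth) order; a trailing group
    with fewer than ``bin_size`` members is kept with ``complete=False``.
    Any minimum-count gate is the consumer's job, not this function's.
    """
    if bin_size < 1:
        raise InvalidInputError("bin_size must be >= 1")
    pooled: list[PooledSeries] = []
    for start in range(0, len(series_list), bin_size):
        group = series_list[start : start + bin_size]
        values = np.concatenate([s.values for s in group]) if group else np.array([])
        depths = [s.depth for s in group if s.depth is not None]
        pooled.append(
            PooledSeries(
                member_sample_ids=[s.sample_id for s in group],
                values=values,
                metric=group[0].metric,
                complete=len(group) == bin_size,
                depth=float(np.mean(depths)) if depths else None,
            )
        )
    return pooled


def nrd0_bandwidth(values: np.ndarray) -> float:
    """Silverman rule-of-thumb bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5).

    This is the classical "rule of thumb" default of R's density(); the IQR
    guard keeps the bandwidth sane for heavy-tailed or bimodal samples.
    """
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(v.mean()), 1.0) * 1e-3
    return 0.9 * spread * v.size ** (-0.2)


def density(
    values: np.ndarray,
    grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    grid_points: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate of a size sample.

    Returns ``(grid, density)``. The default grid spans the data ± 4
    bandwidths (matching common plotting defaults) so the curve integrates
    to 1 within a fraction of a percent.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise InvalidInputError("density requires at least 2 distinct values")
    h = float(bandwidth) if bandwidth is not None else nrd0_bandwidth(v)
    if h <= 0:
        raise InvalidInputError("bandwidth must be > 0")
    if grid is None:
        grid = np.linspace(v.min() - 4 * h, v.max() + 4 * h, grid_points)
    else:
        grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - v[None, :]) / h
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (v.size * h * np.sqrt(2 * np.pi))
    return grid, dens


def summarize(values: np.ndarray) -> SummaryStats:
    """Arithmetic mean, sample SD (n−1) and count of a size sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("summarize requires a non-empty input")
    if v.size == 1:
        return SummaryStats(mean=float(v[0]), sd=0.0, n=1, qc_note="sd_undefined_n1")
    return SummaryStats(mean=float(v.mean()), sd=float(v.std(ddof=1)), n=int(v.size))
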