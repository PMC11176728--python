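"""CSV / JSON input-output helpers for the measurement pipeline."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .sizestats import SampleSeries
from .types import GrainMeasurement

MEASUREMENT_COLUMNS = [
    "grain_id",
    "sample_id",
    "depth",
    "area_um2",
    "mean_width_um",
    "suitable",
    "qc_flags",
]


def measurements_to_frame(
    measurements: Sequence[GrainMeasurement],
    depths: dict[str, float] | None = None,
) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append(
            {
                "grain_id": m.grain_id,
                "sample_id": m.sample_id,
                "depth": (depths or {}).get(m.sample_id, np.nan),
                "area_um2": m.area_um2,
                "mean_width_um": m.mean_width_um,
                "suitable": bool(m.suitable),
                "qc_flags": ";".join(sorted(m.qc_flags)),
            }
        )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"grain_id", "sample_id", "area_um2", "mean_width_um"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"measurement table {path} missing columns {sorted(missing)}")
    if "qc_flags" in df.columns:
        df["qc_flags"] = df["qc_flags"].fillna("")
    return df


def write_profiles(
    profiles: Sequence[tuple[str, np.ndarray]], path: str | Path
) -> None:
    """Companion CSV of full width profiles: grain_id, theta_deg, width_um."""
    rows = []
    for grain_id, widths in profiles:
        n = len(widths)
        for k, w in enumerate(widths):
            rows.append({"grain_id": grain_id, "theta_deg": k * 180.0 / n, "width_um": w})
    pd.DataFrame(rows, columns=["grain_id", "theta_deg", "width_um"]).to_csv(path, index=False)


def series_from_measurements(
    df: pd.DataFrame, metric: str = "mean_width", suitable_only: bool = True
) -> list[SampleSeries]:
    """Group a measurement table into per-sample size series, depth-ordered."""
    col = {"mean_width": "mean_width_um", "area": "area_um2"}.get(metric)
    if col is None:
        raise InvalidInputError(f"metric must be 'mean_width' or 'area', got {metric!r}")
    sub = df
    if suitable_only and "suitable" in df.columns:
        sub = df[df["suitable"].astype(bool)]
    series = []
    for sample_id, g in sub.groupby("sample_id", sort=False):
        depth = None
        if "depth" in g.columns and g["depth"].notna().any():
            depth = float(g["depth"].dropna().iloc[0])
        series.append(
            SampleSeries(sample_id=str(sample_id), values=g[col].to_numpy(float),
                         metric=metric, depth=depth)
        )
    series.sort(key=lambda s: (s.depth is None, s.depth))
    return series


def write_density_curves(
    curves: Sequence[tuple[str, np.ndarray, np.ndarray]], path: str | Path
) -> None:
    """Density-curve CSV (sample_id, grid value, density) for ridgeline plots."""
    rows = []
    for sample_id, grid, dens in curves:
        for x, d in zip(grid, dens):
            rows.append({"sample_id": sample_id, "x": x, "density": d})
    pd.DataFrame(rows, columns=["sample_id", "x", "density"]).to_csv(path, index=False)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_run_manifest(path: str | Path, command: str, config: dict, counts: dict) -> None:
    """Machine-readable record of one CLI run: config, seed, versions, stage counts."""
    import pollensize

    manifest = {
        "command": command,
        "config": _jsonable(config),
        "counts": _jsonable(counts),
        "versions": {
            "pollensize": pollensize.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_run_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
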