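"""Manual-vs-automatic measurement comparison harness.

Joins two measurement tables (e.g. manual outlines vs automatic ones) on a
grain key and reports the squared Pearson correlation plus the distribution
of signed per-grain percent differences (B relative to A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import InvalidInputError


@dataclass
class ComparisonResult:
    r_squared: float
    p_value: float
    differences: pd.DataFrame  # key, value_a, value_b, pct_diff
    n: int

    @property
    def mean_pct_diff(self) -> float:
        return float(self.differences["pct_diff"].mean())


def compare_measurements(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    key: str = "grain_id",
    value_col: str = "mean_width_um",
) -> ComparisonResult:
    """Compare two measurement tables grain by grain.

    Requires at least 3 joined rows. ``pct_diff`` is 100·(B−A)/A.
    """
    for name, t in (("A", table_a), ("B", table_b)):
        for col in (key, value_col):
            if col not in t.columns:
                raise InvalidInputError(f"table {name} lacks column {col!r}")
    joined = table_a[[key, value_col]].merge(
        table_b[[key, value_col]], on=key, suffixes=("_a", "_b")
    )
    if len(joined) < 3:
        raise InvalidInputError(f"only {len(joined)} joined rows; need at least 3")
    a = joined[f"{value_col}_a"].to_numpy(float)
    b = joined[f"{value_col}_b"].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r2, p = 1.0 if np.allclose(a * b.mean(), b * a.mean()) else 0.0, np.nan
    else:
        r, p = pearsonr(a, b)
        r2 = float(r**2)
    diffs = pd.DataFrame(
        {key: joined[key], "value_a": a, "value_b": b, "pct_diff": 100.0 * (b - a) / a}
    )
    return ComparisonResult(r_squared=r2, p_value=float(p) if p == p else float("nan"),
                            differences=diffs, n=len(joined))
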