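"""Packaged reference size parameters for modern birch pollen.

The shipped table holds automatically measured mean/SD of grain area (μm²)
and rotational mean width (μm) for four birch species, all from modern
reference material mounted in silicone oil. Because sample preparation and
mounting medium systematically alter grain size, these parameters are only
valid for fossil material prepared the same way; records mounted in glycerol
need their own reference table.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd

from .errors import InvalidInputError, UnsupportedError
from .unmix import MAX_COMPONENTS, SpeciesComponent

REFERENCE_FILENAME = "betula_reference_silicone.csv"


def reference_path() -> Path:
    return Path(str(files("pollensize").joinpath("data", REFERENCE_FILENAME)))


def load_reference_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a reference CSV (columns: species, metric, mean, sd, n, mounting_medium)."""
    df = pd.read_csv(path if path is not None else reference_path())
    required = {"species", "metric", "mean", "sd"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"reference table missing columns {sorted(missing)}")
    return df


def components_for_metric(
    metric: str,
    species: list[str] | None = None,
    table: pd.DataFrame | None = None,
) -> list[SpeciesComponent]:
    """Build fixed mixture components for one metric from a reference table.

    ``species`` restricts and orders the components (e.g. excluding
    *B. humilis* when it was absent from the study region); at most four
    components are supported by the unmixing stage.
    """
    df = table if table is not None else load_reference_table()
    sub = df[df["metric"] == metric]
    if sub.empty:
        raise InvalidInputError(f"no reference rows for metric {metric!r}")
    if species is not None:
        known = set(sub["species"])
        unknown = [s for s in species if s not in known]
        if unknown:
            raise InvalidInputError(f"species not in reference table: {unknown}")
        sub = sub.set_index("species").loc[species].reset_index()
    if len(sub) > MAX_COMPONENTS:
        raise UnsupportedError(
            f"reference selects {len(sub)} components; at most {MAX_COMPONENTS} supported"
        )
    return [
        SpeciesComponent(name=r.species, mu=float(r.mean), sigma=float(r.sd))
        for r in sub.itertuples()
    ]
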