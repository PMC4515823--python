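"""Raster container and standard-format adapters.

A :class:`Raster` is a 2-D float array on a :class:`~palmx.grid.Grid` with an
explicit nodata mask.  On disk a raster is a single-band TIFF (float32 or
uint8, nodata written as -9999) written via :mod:`tifffile`, accompanied by a
``.json`` sidecar carrying the grid definition, the nodata value and free-form
provenance.  Write-then-read is bit-identical for float32 payloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grid import Grid, NODATA

HABITAT_GROUPS = ("rainforest", "open-habitat", "other")


@dataclass
class Raster:
    grid: Grid
    values: np.ndarray  # float64 working dtype; nodata cells hold NaN
    name: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return np.isfinite(self.values)

    def copy_with(self, values: np.ndarray, name: str | None = None,
                  provenance: dict | None = None) -> "Raster":
        return Raster(self.grid, values, name if name is not None else self.name,
                      dict(provenance if provenance is not None else self.provenance))

    def filled(self, fill: float = NODATA, dtype=np.float32) -> np.ndarray:
        out = self.values.astype(dtype)
        out[~self.mask] = fill
        return out


def write_raster(raster: Raster, path: str | Path, dtype: str = "float32") -> Path:
    """Write a single-band TIFF plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dtype == "uint8":
        data = raster.values.copy()
        data[~raster.mask] = 255  # uint8 nodata code
        arr = data.astype(np.uint8)
        nodata: float = 255
    else:
        arr = raster.filled(NODATA, np.float32)
        nodata = NODATA
    tifffile.imwrite(path, arr)
    sidecar = {
        "grid": raster.grid.to_dict(),
        "nodata": nodata,
        "dtype": dtype,
        "name": raster.name,
        "provenance": raster.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_raster(path: str | Path) -> Raster:
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = Grid.from_dict(sidecar["grid"])
    values = arr.astype(float)
    values[arr == sidecar["nodata"]] = np.nan
    return Raster(grid, values, sidecar.get("name", path.stem),
                  sidecar.get("provenance", {}))


def write_occurrences(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[["species_id", "x", "y", "habitat_group"]].to_csv(path, index=False)
    return path


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read and validate an occurrence CSV (species_id, x, y, habitat_group)."""
    df = pd.read_csv(path)
    required = {"species_id", "x", "y", "habitat_group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"occurrence file missing columns: {sorted(missing)}")
    bad = df[~df["habitat_group"].isin(HABITAT_GROUPS)]
    if len(bad):
        rows = bad.index.tolist()[:20]
        raise ValueError(
            f"unknown habitat group in rows {rows}: "
            f"{sorted(bad['habitat_group'].unique())} (allowed: {HABITAT_GROUPS})"
        )
    return df
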