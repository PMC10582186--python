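"""Raster and table I/O plus the dataset naming protocol.

Rasters are single-band float32 TIFF files. Grid geometry (top-left origin,
cell size, CRS tag, nodata) and units travel in the TIFF description tag as
JSON and, at dataset level, in a ``manifest.yaml`` next to the files. A
published dataset is organized as ``<region>/<year>.tif`` with contiguous
years per region.

Tabular inputs are UTF-8 CSV with a required header; units are never
implicit — they are either a declared schema constant or passed explicitly
and converted on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

#: conversion factor for annual per-capita masses to daily grams
KG_PER_YEAR_TO_G_PER_DAY = 1000.0 / 365.0

#: default nodata for float rasters and the zone-grid sentinel
NODATA = -9999.0
NO_ZONE = -9999

UNITS_EDI = "ug kg-1 d-1"


class SchemaError(ValueError):
    """A table failed schema validation; the message names the offence."""


@dataclass(frozen=True)
class GridGeometry:
    """North-up, row-major grid geometry for all rasters of a study region."""

    rows: int
    cols: int
    cell_size: float = 1000.0  # metres
    x_origin: float = 0.0  # top-left corner
    y_origin: float = 0.0
    crs: str = "local"
    nodata: float = NODATA

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridGeometry":
        return cls(**dict(d))


def write_raster(
    path: str | Path,
    array: np.ndarray,
    geometry: GridGeometry,
    units: str = UNITS_EDI,
    overwrite: bool = False,
    extra_tags: Mapping[str, str] | None = None,
) -> Path:
    """Write a single-band float32 raster with geometry/units in metadata."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    arr = np.asarray(array, dtype=np.float32)
    if arr.shape != (geometry.rows, geometry.cols):
        raise ValueError(
            f"array shape {arr.shape} does not match geometry "
            f"({geometry.rows}, {geometry.cols})"
        )
    meta = {"geometry": geometry.to_dict(), "units": units}
    if extra_tags:
        meta.update(extra_tags)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, arr, description=json.dumps(meta))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, GridGeometry, dict]:
    """Read a raster written by :func:`write_raster`.

    Returns ``(array, geometry, metadata)``; the array is float32.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    geom = GridGeometry.from_dict(meta["geometry"]) if "geometry" in meta else None
    if geom is None:
        geom = GridGeometry(rows=arr.shape[0], cols=arr.shape[1])
    return np.asarray(arr, dtype=np.float32), geom, meta


@dataclass
class DatasetManifest:
    """Description of a published gridded-exposure dataset.

    Every (region, year) pair maps to exactly one ``<region>/<year>.tif``
    file; years are contiguous within the declared range.
    """

    regions: list[str]
    year_start: int
    year_end: int
    units: str = UNITS_EDI
    path_pattern: str = "{region}/{year}.tif"
    geometry: GridGeometry | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    def file_path(self, region: str, year: int) -> str:
        return self.path_pattern.format(region=region, year=year)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "regions": self.regions,
            "year_start": self.year_start,
            "year_end": self.year_end,
            "units": self.units,
            "path_pattern": self.path_pattern,
            "geometry": self.geometry.to_dict() if self.geometry else None,
            "provenance": self.provenance,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetManifest":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        geom = d.pop("geometry", None)
        m = cls(**{k: v for k, v in d.items() if k != "geometry"})
        if geom:
            m.geometry = GridGeometry.from_dict(geom)
        return m


def write_dataset(
    rasters: Mapping[tuple[str, int], np.ndarray],
    manifest: DatasetManifest,
    outdir: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write all rasters of a dataset plus its manifest.

    Raises with an explicit listing if any (region, year) pair declared in
    the manifest is missing from ``rasters``.
    """
    missing = [
        (r, y) for r in manifest.regions for y in manifest.years if (r, y) not in rasters
    ]
    if missing:
        gaps = ", ".join(f"{r}/{y}" for r, y in missing)
        raise ValueError(f"missing rasters for: {gaps}")
    outdir = Path(outdir)
    geom = manifest.geometry
    if geom is None:
        first = next(iter(rasters.values()))
        geom = GridGeometry(rows=first.shape[0], cols=first.shape[1])
        manifest.geometry = geom
    for region in manifest.regions:
        for year in manifest.years:
            write_raster(
                outdir / manifest.file_path(region, year),
                rasters[(region, year)],
                geom,
                units=manifest.units,
                overwrite=overwrite,
            )
    mpath = outdir / "manifest.yaml"
    if mpath.exists() and not overwrite:
        raise FileExistsError(f"{mpath} exists; pass overwrite=True")
    manifest.to_yaml(mpath)
    return outdir


def read_dataset(outdir: str | Path) -> tuple[dict[tuple[str, int], np.ndarray], DatasetManifest]:
    """Round-trip a dataset written by :func:`write_dataset`."""
    outdir = Path(outdir)
    manifest = DatasetManifest.from_yaml(outdir / "manifest.yaml")
    rasters = {}
    for region in manifest.regions:
        for year in manifest.years:
            arr, _, _ = read_raster(outdir / manifest.file_path(region, year))
            rasters[(region, year)] = arr
    return rasters, manifest


# ---------------------------------------------------------------------------
# tabular schemas

_YEAR_RANGE = (1950, 2100)

#: required columns per logical table
TABLE_SCHEMAS: dict[str, list[str]] = {
    "concentrations": ["food", "year", "value_ug_per_kg", "source"],
    "consumption": ["city", "sector", "food", "value"],
    "national_ratios": ["food", "national_intake", "national_consumption"],
    "counties": ["county", "city", "urbanization_rate", "population", "per_capita_gdp"],
    "expenditure": ["county", "pcon"],
    "county_edi": ["county", "year", "edi"],
}


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table '{name}' is missing columns {missing}")


def read_table(path: str | Path, schema: str, units: str | None = None) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    For the ``consumption`` schema, ``units`` must be ``'kg_per_year'`` or
    ``'g_per_day'``; annual values are converted to g d⁻¹ capita⁻¹ on read
    and the returned frame always carries g/d values in ``value``.
    """
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown schema '{schema}'")
    df = pd.read_csv(path)
    _require_columns(df, TABLE_SCHEMAS[schema], schema)

    if schema == "concentrations":
        bad = df[df["value_ug_per_kg"] < 0]
        if not bad.empty:
            row = bad.index[0]
            raise SchemaError(
                f"negative concentration at row {row}: "
                f"{bad.loc[row, 'food']} {bad.loc[row, 'year']}"
            )
        years = df["year"]
        if ((years < _YEAR_RANGE[0]) | (years > _YEAR_RANGE[1])).any():
            raise SchemaError(f"year outside plausible range {_YEAR_RANGE}")
    elif schema == "consumption":
        if units not in ("kg_per_year", "g_per_day"):
            raise SchemaError(
                "consumption tables require units='kg_per_year' or 'g_per_day'"
            )
        if (df["value"] < 0).any():
            raise SchemaError("negative consumption value")
        bad_sector = set(df["sector"]) - {"urban", "rural"}
        if bad_sector:
            raise SchemaError(f"unknown sector labels: {sorted(bad_sector)}")
        if units == "kg_per_year":
            df = df.assign(value=df["value"] * KG_PER_YEAR_TO_G_PER_DAY)
    elif schema == "national_ratios":
        if (df["national_consumption"] <= 0).any():
            raise SchemaError("national_consumption must be > 0")
        if (df["national_intake"] < 0).any():
            raise SchemaError("national_intake must be >= 0")
    elif schema == "counties":
        r = df["urbanization_rate"]
        if ((r < 0) | (r > 1)).any():
            raise SchemaError("urbanization_rate outside [0, 1]")
        if (df["population"] <= 0).any():
            raise SchemaError("population must be > 0")
    return df
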