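"""Gridded sea-surface δ¹⁸O isoscape: I/O, CI assignment masks, summaries.

Geographic assignment is pure value extraction: a grid cell is consistent
with a whale when the cell's seawater δ¹⁸O lies inside the whale's
confidence interval for source δ¹⁸O_marine.  The interval is closed on both
ends, land/no-data cells are never assignable, and no interpolation is
performed.  Only the estimate-side variance enters the interval; variance of
the isoscape product itself is not modelled.

Grids are stored with cell-center coordinates, latitude normalised
ascending, and longitude wrapped to [−180, 180).  NetCDF (1-D ``lat``/``lon``
coordinate variables plus a 2-D value variable, default name ``d18o``) and a
CSV dialect (first row longitudes, first column latitudes) are supported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import xarray as xr

__all__ = [
    "IsoscapeGrid",
    "AssignmentMask",
    "MaskSummary",
    "FormatError",
    "EmptyGridError",
    "IntervalError",
    "read_isoscape",
    "write_isoscape",
    "assign_interval",
    "assign_specimens",
    "mask_summary",
    "write_masks",
]


class FormatError(ValueError):
    """The file does not contain the expected coordinate/value variables."""


class EmptyGridError(ValueError):
    """Every cell of the grid is missing."""


class IntervalError(ValueError):
    """Interval bounds are inverted (lo > hi)."""


def _wrap_lon(lon: np.ndarray) -> np.ndarray:
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class IsoscapeGrid:
    """Seawater δ¹⁸O (‰ VSMOW) on a lat × lon cell-center grid.

    ``values`` has shape ``(len(lat), len(lon))``; ``missing`` is a boolean
    array of the same shape marking land/no-data cells.  Latitude is
    ascending; longitude is wrapped to [−180, 180) but kept in file order.
    """

    lat: np.ndarray
    lon: np.ndarray
    values: np.ndarray
    missing: np.ndarray

    def __post_init__(self):
        lat = np.asarray(self.lat, dtype=float)
        lon = _wrap_lon(self.lon)
        values = np.asarray(self.values, dtype=float)
        missing = np.asarray(self.missing, dtype=bool) | ~np.isfinite(values)
        if values.shape != (lat.size, lon.size) or missing.shape != values.shape:
            raise ValueError("inconsistent grid shapes")
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitudes must lie in [-90, 90]")
        if lat.size > 1 and np.any(np.diff(lat) < 0):  # normalise ascending
            order = np.argsort(lat, kind="stable")
            lat, values, missing = lat[order], values[order], missing[order]
        if missing.all():
            raise EmptyGridError("grid has no non-missing cells")
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "missing", missing)

    @property
    def n_valid(self) -> int:
        return int((~self.missing).sum())


@dataclass(frozen=True)
class AssignmentMask:
    """Boolean cell set consistent with one specimen's CI."""

    specimen_id: str
    interval: tuple[float, float]
    mask: np.ndarray
    n_cells: int
    empty: bool


@dataclass(frozen=True)
class MaskSummary:
    specimen_id: str
    n_cells: int
    fraction: float
    empty: bool
    lat_min: float | None
    lat_max: float | None
    lat_mean: float | None
    value_min: float | None
    value_max: float | None


def read_isoscape(path: str | Path, config: dict | None = None) -> IsoscapeGrid:
    """Read a grid from NetCDF or CSV, normalising orientation and missing data.

    ``config`` may remap NetCDF variable names (keys ``lat``, ``lon``,
    ``values``; defaults ``lat``, ``lon``, ``d18o``).  NaN and fill values
    become missing cells.
    """
    path = Path(path)
    if path.suffix.lower() in (".csv", ".txt"):
        return _read_csv_grid(path)
    names = {"lat": "lat", "lon": "lon", "values": "d18o"}
    names.update(config or {})
    with xr.open_dataset(path) as ds:
        for key in ("lat", "lon"):
            if names[key] not in ds.variables:
                raise FormatError(f"missing coordinate variable {names[key]!r}")
        if names["values"] not in ds.variables:
            raise FormatError(f"missing value variable {names['values']!r}")
        lat = ds[names["lat"]].values.astype(float)
        lon = ds[names["lon"]].values.astype(float)
        var = ds[names["values"]]
        vals = var.values.astype(float)
        if vals.shape == (lon.size, lat.size) and lat.size != lon.size:
            vals = vals.T
    return IsoscapeGrid(lat=lat, lon=lon, values=vals, missing=~np.isfinite(vals))


def _read_csv_grid(path: Path) -> IsoscapeGrid:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2 or len(rows[0]) < 2:
        raise FormatError("CSV grid needs a longitude header row and latitude column")
    lon = np.array([float(c) for c in rows[0][1:]])
    lat, data = [], []
    for row in rows[1:]:
        lat.append(float(row[0]))
        data.append([float(c) if c.strip() != "" and c.strip().lower() != "nan" else np.nan for c in row[1:]])
    vals = np.array(data, dtype=float)
    return IsoscapeGrid(lat=np.array(lat), lon=lon, values=vals, missing=~np.isfinite(vals))


def write_isoscape(grid: IsoscapeGrid, path: str | Path, names: dict | None = None) -> None:
    """Write a grid to NetCDF (by suffix ``.nc``) or the CSV dialect."""
    path = Path(path)
    if path.suffix.lower() in (".csv", ".txt"):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["lat\\lon"] + [repr(float(v)) for v in grid.lon])
            vals = np.where(grid.missing, np.nan, grid.values)
            for i, la in enumerate(grid.lat):
                writer.writerow([repr(float(la))] + ["" if not np.isfinite(v) else repr(float(v)) for v in vals[i]])
        return
    nm = {"lat": "lat", "lon": "lon", "values": "d18o"}
    nm.update(names or {})
    vals = np.where(grid.missing, np.nan, grid.values)
    ds = xr.Dataset(
        {nm["values"]: ((nm["lat"], nm["lon"]), vals)},
        coords={nm["lat"]: grid.lat, nm["lon"]: grid.lon},
        attrs={"units": "permil VSMOW", "convention": "cell-center"},
    )
    ds.to_netcdf(path)


def assign_interval(grid: IsoscapeGrid, interval: tuple[float, float], specimen_id: str = "") -> AssignmentMask:
    """Cells whose δ¹⁸O lies in the closed interval [lo, hi].

    Missing cells never qualify.  ``empty`` is set when no cell qualifies
    (e.g. a CI lying entirely above the grid maximum).
    """
    lo, hi = interval
    if lo > hi:
        raise IntervalError(f"lo ({lo}) > hi ({hi})")
    with np.errstate(invalid="ignore"):
        mask = (~grid.missing) & (grid.values >= lo) & (grid.values <= hi)
    n = int(mask.sum())
    return AssignmentMask(specimen_id=specimen_id, interval=(float(lo), float(hi)), mask=mask, n_cells=n, empty=n == 0)


def assign_specimens(estimates: Sequence, grid: IsoscapeGrid) -> list[AssignmentMask]:
    """One mask per marine estimate, using its (ci_lo, ci_hi); order preserved."""
    return [assign_interval(grid, (e.ci_lo, e.ci_hi), specimen_id=e.specimen_id) for e in estimates]


def mask_summary(mask: AssignmentMask, grid: IsoscapeGrid) -> MaskSummary:
    """Cell count, assigned fraction of the valid grid, and latitude/value stats."""
    if mask.mask.shape != grid.values.shape:
        raise ValueError("mask and grid shapes disagree")
    frac = mask.n_cells / grid.n_valid if grid.n_valid else 0.0
    if mask.n_cells == 0:
        return MaskSummary(mask.specimen_id, 0, 0.0, True, None, None, None, None, None)
    rows, _ = np.nonzero(mask.mask)
    lats = grid.lat[rows]
    vals = grid.values[mask.mask]
    return MaskSummary(
        specimen_id=mask.specimen_id,
        n_cells=mask.n_cells,
        fraction=float(frac),
        empty=False,
        lat_min=float(lats.min()),
        lat_max=float(lats.max()),
        lat_mean=float(lats.mean()),
        value_min=float(vals.min()),
        value_max=float(vals.max()),
    )


def write_masks(masks: Sequence[AssignmentMask], grid: IsoscapeGrid, path: str | Path) -> None:
    """Write all masks as boolean layers of one NetCDF file (dim ``specimen``)."""
    if not masks:
        raise ValueError("no masks to write")
    data = np.stack([m.mask for m in masks]).astype("i1")
    ds = xr.Dataset(
        {"assigned": (("specimen", "lat", "lon"), data)},
        coords={
            "specimen": [m.specimen_id for m in masks],
            "lat": grid.lat,
            "lon": grid.lon,
        },
    )
    ds.to_netcdf(path)
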