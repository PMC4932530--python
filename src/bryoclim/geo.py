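"""Raster, occurrence and polygon I/O on a single shared geographic grid.

All spatial data in the package lives on one regular lon/lat grid addressed
as ``(row, col)`` with row 0 at the northern edge.  This module owns every
coordinate convention; no other module re-derives geography from lon/lat.

Cells are half-open intervals ``[west, west + cell) x (north - cell, north]``:
a point on a shared vertical edge belongs to the cell whose west edge it is,
and a point on a shared horizontal edge to the cell whose north edge it is.

Rasters are read and written as ESRI ASCII grids (plain text, one band per
file); occurrences as CSV with a ``species, lon, lat`` header; protected
areas as GeoJSON polygons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping as shapely_mapping, shape as shapely_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

NODATA = -9999.0


class GridError(ValueError):
    """Raised for mis-registered rasters or out-of-bounds coordinates."""


@dataclass(frozen=True)
class GridTransform:
    """Geotransform of a north-up regular lon/lat grid.

    ``west``/``north`` are the coordinates of the outer corner of cell
    ``(0, 0)``; ``cell_size`` is in decimal degrees (0.0083 deg is roughly a
    1-km^2 pixel at these latitudes, the resolution convention used
    throughout).
    """

    west: float
    north: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise GridError(f"cell_size must be positive, got {self.cell_size}")

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Return (lon, lat) of the centre of a cell."""
        lon = self.west + (col + 0.5) * self.cell_size
        lat = self.north - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_box(self, row: int, col: int) -> tuple[float, float, float, float]:
        """Return (west, south, east, north) bounds of a cell."""
        w = self.west + col * self.cell_size
        n = self.north - row * self.cell_size
        return w, n - self.cell_size, w + self.cell_size, n


def lonlat_to_cell(
    lon: float, lat: float, transform: GridTransform, shape: tuple[int, int]
) -> tuple[int, int]:
    """Map a point to the (row, col) of the cell containing it.

    Follows the half-open convention documented in the module docstring.
    Raises :class:`GridError` if the point falls outside the grid.
    """
    n_rows, n_cols = shape
    dx = (lon - transform.west) / transform.cell_size
    dy = (transform.north - lat) / transform.cell_size
    col = int(np.floor(dx))
    # latitude intervals are open at the bottom, closed at the top
    row = 0 if dy <= 0 else int(np.ceil(dy)) - 1
    if dy < 0 or not (0 <= col < n_cols) or not (0 <= row < n_rows):
        raise GridError(
            f"point ({lon}, {lat}) outside grid of shape {shape} "
            f"with origin ({transform.west}, {transform.north})"
        )
    return row, col


@dataclass
class ClimateStack:
    """Co-registered named climate grids plus elevation and a validity mask.

    Invariants: all grids share one shape; ``valid_mask`` is False wherever
    any variable (or elevation) is missing; only valid cells take part in
    modelling, projection and counting.
    """

    variables: dict[str, np.ndarray]
    elevation: np.ndarray
    transform: GridTransform
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {name: g.shape for name, g in self.variables.items()}
        shapes["elevation"] = self.elevation.shape
        shapes["valid_mask"] = self.valid_mask.shape
        if len(set(shapes.values())) != 1:
            raise GridError(f"grids are not co-registered: {shapes}")
        # missing data in any layer invalidates the cell
        bad = ~np.isfinite(self.elevation)
        for g in self.variables.values():
            bad |= ~np.isfinite(g)
        self.valid_mask = self.valid_mask & ~bad

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def variable_names(self) -> list[str]:
        return list(self.variables)

    def env_at(self, cells: Sequence[tuple[int, int]], names: Sequence[str]) -> np.ndarray:
        """Environment matrix (len(cells) x len(names)) at the given cells."""
        rows = np.array([c[0] for c in cells], dtype=int)
        cols = np.array([c[1] for c in cells], dtype=int)
        return np.column_stack([self.variables[n][rows, cols] for n in names])

    def valid_cells(self) -> list[tuple[int, int]]:
        r, c = np.nonzero(self.valid_mask)
        return list(zip(r.tolist(), c.tolist()))

    def copy(self) -> "ClimateStack":
        return ClimateStack(
            variables={k: v.copy() for k, v in self.variables.items()},
            elevation=self.elevation.copy(),
            transform=self.transform,
            valid_mask=self.valid_mask.copy(),
        )


@dataclass
class RegionMask:
    """Per-cell region labels: island id, archipelago id, continent flag.

    ``island_id`` and ``archipelago_id`` are 0 where the cell is not an
    island cell; ids are positive integers.  Every island cell must carry an
    archipelago label.
    """

    island_id: np.ndarray
    archipelago_id: np.ndarray
    continent: np.ndarray

    def __post_init__(self) -> None:
        if not (self.island_id.shape == self.archipelago_id.shape == self.continent.shape):
            raise GridError("region grids are not co-registered")
        orphan = (self.island_id > 0) & (self.archipelago_id == 0)
        if orphan.any():
            raise GridError(f"{int(orphan.sum())} island cells lack an archipelago label")

    @property
    def n_islands(self) -> int:
        return int(self.island_id.max())

    @property
    def island_ids(self) -> list[int]:
        return sorted(int(i) for i in np.unique(self.island_id) if i > 0)

    @property
    def archipelago_ids(self) -> list[int]:
        return sorted(int(i) for i in np.unique(self.archipelago_id) if i > 0)

    @property
    def is_island(self) -> np.ndarray:
        return self.island_id > 0

    @property
    def is_land(self) -> np.ndarray:
        return self.is_island | self.continent


@dataclass
class OccurrenceSet:
    """Grid-snapped, deduplicated presence cells for one species."""

    species: str
    cells: set = field(default_factory=set)
    n_raw: int = 0

    def __post_init__(self) -> None:
        self.cells = {(int(r), int(c)) for r, c in self.cells}

    def __len__(self) -> int:
        return len(self.cells)

    def sorted_cells(self) -> list[tuple[int, int]]:
        return sorted(self.cells)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_grid(grid: np.ndarray, transform: GridTransform, path: str | Path) -> None:
    """Write one grid as an ESRI ASCII raster; NaN becomes the nodata code."""
    n_rows, n_cols = grid.shape
    yll = transform.north - n_rows * transform.cell_size
    out = np.where(np.isfinite(grid), grid, NODATA)
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {transform.west!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {transform.cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.17g")


def read_grid(path: str | Path) -> tuple[np.ndarray, GridTransform]:
    """Read an ESRI ASCII raster; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if grid.shape != (n_rows, n_cols):
        raise GridError(f"{path}: body shape {grid.shape} != header ({n_rows}, {n_cols})")
    nodata = header.get("nodata_value", NODATA)
    grid = np.where(grid == nodata, np.nan, grid)
    transform = GridTransform(
        west=header["xllcorner"],
        north=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
    )
    return grid, transform


def load_stack(
    variable_paths: Mapping[str, str | Path], elevation_path: str | Path
) -> ClimateStack:
    """Assemble a ClimateStack from per-variable rasters plus elevation.

    All rasters must be co-registered (same shape; geotransforms equal within
    1e-9 deg); a mismatch raises :class:`GridError` naming the layer.
    """
    elev, ref_t = read_grid(elevation_path)
    variables: dict[str, np.ndarray] = {}
    for name, path in variable_paths.items():
        grid, t = read_grid(path)
        if grid.shape != elev.shape:
            raise GridError(f"layer '{name}': shape {grid.shape} != {elev.shape}")
        if (
            abs(t.west - ref_t.west) > 1e-9
            or abs(t.north - ref_t.north) > 1e-9
            or abs(t.cell_size - ref_t.cell_size) > 1e-9
        ):
            raise GridError(f"layer '{name}': geotransform {t} != {ref_t}")
        variables[name] = grid
    valid = np.ones(elev.shape, dtype=bool)
    return ClimateStack(variables=variables, elevation=elev, transform=ref_t, valid_mask=valid)


# ---------------------------------------------------------------------------
# occurrences and polygons


def write_occurrences_csv(
    records: Iterable[tuple[str, float, float]], path: str | Path
) -> None:
    df = pd.DataFrame(records, columns=["species", "lon", "lat"])
    df.to_csv(path, index=False)


def read_occurrences_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"species", "lon", "lat"} - set(df.columns)
    if missing:
        raise GridError(f"{path}: occurrence CSV lacks columns {sorted(missing)}")
    return df


def occurrence_lonlat(occ: OccurrenceSet, transform: GridTransform) -> pd.DataFrame:
    """Cell-centre lon/lat table for an OccurrenceSet (for CSV export)."""
    rows = [
        (occ.species, *transform.cell_center(r, c)) for r, c in occ.sorted_cells()
    ]
    return pd.DataFrame(rows, columns=["species", "lon", "lat"])


def write_polygons_geojson(polygons: Sequence[BaseGeometry], path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"id": i}, "geometry": shapely_mapping(p)}
        for i, p in enumerate(polygons)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_polygons_geojson(path: str | Path) -> list[BaseGeometry]:
    with open(path) as fh:
        doc = json.load(fh)
    return [shapely_shape(f["geometry"]) for f in doc["features"]]
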