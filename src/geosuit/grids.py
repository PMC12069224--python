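"""Grid geometry, raster layers and covariate stacks.

The whole package works on one rectangular geographic grid: row 0 is the
northern edge, cells are ``cell_size`` degrees square and half-open in both
axes, so a point on a cell's eastern or southern boundary belongs to the next
cell. Rasters are stored as single-band ESRI ASCII grids (plain text), one
file per layer, tied together by a JSON manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "CovariateStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "FAMILIES",
]

FAMILIES = ("bioclim", "topo", "vegetation", "human", "radiation")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up geographic raster grid.

    ``origin_lon``/``origin_lat`` locate the grid's top-left corner (north-west).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_rows * self.n_cols < 4:
            raise ValueError("grid must have at least 4 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_center(self, i, j):
        """Lon/lat of the centre of cell (row i, col j)."""
        i = np.asarray(i)
        j = np.asarray(j)
        lon = self.origin_lon + (j + 0.5) * self.cell_size
        lat = self.origin_lat - (i + 0.5) * self.cell_size
        return lon, lat

    def cell_of(self, lon, lat):
        """Row/col of the cell containing a point; may fall off-grid.

        Cells are half-open: [west, east) x (south, north], rendered row-major
        from the north, which makes the floor rule below exact.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        j = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        i = np.floor((self.origin_lat - lat) / self.cell_size).astype(int)
        return i, j

    def in_bounds(self, i, j):
        i = np.asarray(i)
        j = np.asarray(j)
        return (i >= 0) & (i < self.n_rows) & (j >= 0) & (j < self.n_cols)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_size": self.cell_size,
            "origin_lon": self.origin_lon,
            "origin_lat": self.origin_lat,
            "nodata_value": self.nodata_value,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSpec":
        return cls(**{k: d[k] for k in (
            "n_rows", "n_cols", "cell_size", "origin_lon", "origin_lat", "nodata_value")})


def write_ascii_grid(values: np.ndarray, grid: GridSpec, path) -> None:
    """Write one layer as an ESRI ASCII grid (rows north to south)."""
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"layer shape {values.shape} does not match grid {grid.shape}")
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon!r}\n"
        f"yllcorner {grid.origin_lat - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata_value!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        if np.issubdtype(values.dtype, np.integer):
            np.savetxt(fh, values, fmt="%d")
        else:
            np.savetxt(fh, values, fmt="%.9g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read a single-band ESRI ASCII grid back into (values, GridSpec)."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
        nodata_value=header.get("nodata_value", -9999.0),
    )
    values = np.atleast_2d(values)
    if values.shape != grid.shape:
        raise ValueError(f"raster body {values.shape} does not match header {grid.shape}")
    return values, grid


@dataclass
class CovariateStack:
    """Named, co-registered raster layers on one grid with a validity mask.

    Layers are dense ``(n_rows, n_cols)`` float arrays; masked-out cells hold
    the grid's nodata value in every layer.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    family: dict[str, str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        for name, layer in self.layers.items():
            if layer.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape does not match grid")
            if name not in self.family:
                raise ValueError(f"layer {name!r} has no family")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def table(self, names: Iterable[str] | None = None) -> pd.DataFrame:
        """Masked-in cells as a design table (one row per valid cell).

        The index is the flattened cell id ``i * n_cols + j``.
        """
        names = list(names) if names is not None else self.names
        idx = np.flatnonzero(self.mask.ravel())
        data = {n: self.layers[n].ravel()[idx] for n in names}
        return pd.DataFrame(data, index=idx)

    def values_at(self, lon, lat, names: Iterable[str] | None = None) -> pd.DataFrame:
        """Covariate values at the cells containing the given points.

        Off-grid or masked-out points yield NaN rows.
        """
        names = list(names) if names is not None else self.names
        i, j = self.grid.cell_of(lon, lat)
        ok = self.grid.in_bounds(i, j)
        ok = ok & self.mask[np.clip(i, 0, self.grid.n_rows - 1),
                            np.clip(j, 0, self.grid.n_cols - 1)]
        out = np.full((np.size(i), len(names)), np.nan)
        ii, jj = np.atleast_1d(i)[np.atleast_1d(ok)], np.atleast_1d(j)[np.atleast_1d(ok)]
        for c, n in enumerate(names):
            out[np.atleast_1d(ok), c] = self.layers[n][ii, jj]
        return pd.DataFrame(out, columns=names)

    # ---- persistence -----------------------------------------------------

    def write(self, out_dir) -> Path:
        """Write one ASCII raster per layer plus a JSON manifest; returns manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, layer in self.layers.items():
            write_ascii_grid(layer, self.grid, out_dir / f"{name}.asc")
        write_ascii_grid(self.mask.astype(int), self.grid, out_dir / "_mask.asc")
        manifest = {
            "grid": self.grid.to_dict(),
            "layers": [{"name": n, "family": self.family[n], "file": f"{n}.asc"}
                       for n in self.names],
            "mask_file": "_mask.asc",
        }
        mpath = out_dir / "stack.json"
        mpath.write_text(json.dumps(manifest, indent=2) + "\n")
        return mpath

    @classmethod
    def read(cls, manifest_path) -> "CovariateStack":
        manifest_path = Path(manifest_path)
        manifest = json.loads(manifest_path.read_text())
        grid = GridSpec.from_dict(manifest["grid"])
        layers: dict[str, np.ndarray] = {}
        family: dict[str, str] = {}
        for entry in manifest["layers"]:
            vals, lgrid = read_ascii_grid(manifest_path.parent / entry["file"])
            if not _grids_close(lgrid, grid):
                raise ValueError(f"layer {entry['name']!r} grid mismatch with manifest")
            layers[entry["name"]] = vals
            family[entry["name"]] = entry["family"]
        mask_vals, _ = read_ascii_grid(manifest_path.parent / manifest["mask_file"])
        return cls(grid=grid, layers=layers, family=family, mask=mask_vals.astype(bool))


def _grids_close(a: GridSpec, b: GridSpec, rtol: float = 1e-9) -> bool:
    return (
        a.n_rows == b.n_rows
        and a.n_cols == b.n_cols
        and math.isclose(a.cell_size, b.cell_size, rel_tol=rtol)
        and math.isclose(a.origin_lon, b.origin_lon, rel_tol=rtol, abs_tol=1e-9)
        and math.isclose(a.origin_lat, b.origin_lat, rel_tol=rtol, abs_tol=1e-9)
    )
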