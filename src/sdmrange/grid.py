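"""Raster grid container and text-raster I/O.

A :class:`Grid` is one georeferenced single-band raster: a 2-D value array,
a nodata mask, an affine-free geotransform (north-up geographic grids only:
origin + square cell size in decimal degrees) and a CRS identifier.  A
:class:`PredictorStack` is a named, mutually aligned set of grids — the
in-memory form of a directory of bioclim/topography layers.

Rasters are read and written in the ESRI ASCII grid format (``.asc``), a
plain-text single-band raster interchange format understood by GIS tools
and by R's ``raster`` package.  The CRS identifier travels in a ``.prj``
sidecar-style comment line is *not* used; instead the package assumes
geographic WGS84 (``EPSG:4326``) unless told otherwise, which matches the
5-arcminute global grids this pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = ["Grid", "PredictorStack", "read_ascii_grid", "write_ascii_grid"]

WGS84 = "EPSG:4326"

#: meters per degree of latitude (spherical approximation used throughout)
M_PER_DEG = 111_320.0


@dataclass
class Grid:
    """One single-band north-up geographic raster.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Cell values, float. Row 0 is the northernmost row.
    nodata_mask : ndarray of bool, same shape
        True where the cell holds no data.
    origin_lon, origin_lat : float
        Coordinates of the *outer corner* of the upper-left cell (degrees).
    cell_size : float
        Square cell edge, decimal degrees. Must be positive.
    crs : str
        CRS identifier; geographic lat/lon only.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    origin_lon: float
    origin_lat: float
    cell_size: float
    crs: str = WGS84

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if not self.cell_size > 0:
            raise ValueError("cell size must be positive")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def transform(self) -> tuple[float, float, float]:
        """(origin_lon, origin_lat, cell_size) — the full geotransform."""
        return (self.origin_lon, self.origin_lat, self.cell_size)

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int):
        """Lon/lat of cell centers for (row, col) indices."""
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each lon/lat point."""
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_size)
        row = np.floor((self.origin_lat - np.asarray(lat)) / self.cell_size)
        return row.astype(int), col.astype(int)

    def lon_lat_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_center(rows, cols)

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.origin_lon, other.origin_lon)
            and np.isclose(self.origin_lat, other.origin_lat)
            and np.isclose(self.cell_size, other.cell_size)
            and self.crs == other.crs
        )

    # -- data -------------------------------------------------------------

    def masked(self) -> np.ndarray:
        """Values with nodata as NaN."""
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def copy(self, values: np.ndarray | None = None,
             nodata_mask: np.ndarray | None = None) -> "Grid":
        return replace(
            self,
            values=(self.values if values is None else values).copy(),
            nodata_mask=(self.nodata_mask if nodata_mask is None else nodata_mask).copy(),
        )


@dataclass
class PredictorStack:
    """Named mapping of mutually aligned grids (e.g. bio_2 … slope)."""

    layers: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not g.aligned_with(grids[0]):
                raise ValueError("stack layers are not mutually aligned")

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> Grid:
        return next(iter(self.layers.values()))

    def combined_nodata(self) -> np.ndarray:
        """True wherever *any* layer is nodata."""
        mask = np.zeros(self.template.shape, dtype=bool)
        for g in self.layers.values():
            mask |= g.nodata_mask
        return mask

    def to_table(self, rows: np.ndarray, cols: np.ndarray,
                 names: list[str] | None = None) -> np.ndarray:
        """Predictor matrix (len(rows) × n_layers) at the given cells."""
        names = names or self.names
        return np.column_stack([self.layers[n].values[rows, cols] for n in names])

    def subset(self, names: list[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return PredictorStack({n: self.layers[n] for n in names})

    def map_values(self) -> dict[str, np.ndarray]:
        return {n: g.values for n, g in self.layers.items()}


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: Grid, path: str | Path, nodata_value: float = -9999.0,
                     fmt: str = "%.8g") -> None:
    """Write a grid as an ESRI ASCII raster (plain text)."""
    path = Path(path)
    vals = grid.values.copy()
    vals[grid.nodata_mask] = nodata_value
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon!r}\n"
        f"yllcorner {grid.origin_lat - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata_value!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def read_ascii_grid(path: str | Path, crs: str = WGS84) -> Grid:
    """Read an ESRI ASCII raster into a :class:`Grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} missing header field {key!r}")
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"ASCII grid {path}: data shape {values.shape} does not "
                         f"match header ({n_rows}, {n_cols})")
    nodata = header.get("nodata_value", -9999.0)
    mask = np.isclose(values, nodata) | ~np.isfinite(values)
    return Grid(
        values=values,
        nodata_mask=mask,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        crs=crs,
    )


def write_stack(stack: PredictorStack, directory: str | Path) -> list[Path]:
    """Write every layer of a stack as ``<name>.asc`` under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, g in stack.layers.items():
        p = directory / f"{name}.asc"
        write_ascii_grid(g, p)
        paths.append(p)
    return paths


def read_stack(directory: str | Path, names: list[str] | None = None,
               crs: str = WGS84) -> PredictorStack:
    """Read ``<name>.asc`` layers from *directory* into a stack."""
    directory = Path(directory)
    if names is None:
        names = sorted(p.stem for p in directory.glob("*.asc"))
    layers = {n: read_ascii_grid(directory / f"{n}.asc", crs=crs) for n in names}
    if not layers:
        raise FileNotFoundError(f"no .asc layers found in {directory}")
    return PredictorStack(layers)
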