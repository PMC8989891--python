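"""Minimal geographic raster containers on a regular lon/lat grid.

All layers in an analysis share a single :class:`GridSpec` (geographic
coordinates, EPSG:4326, row-major indexing from the upper-left corner).
Rasters are stored as NumPy arrays with an explicit NoData sentinel and are
serialized as Arc/Info ASCII grids (plain text) with a small JSON sidecar
carrying the layer name, CRS and value kind.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "Raster", "EnvStack", "read_ascii_grid", "EARTH_RADIUS_KM"]

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid.

    ``origin`` is the (lon, lat) of the *upper-left corner* of the upper-left
    cell. Cell (row, col) covers the half-open box
    ``[origin_lon + col*res, origin_lon + (col+1)*res)`` in longitude and
    ``(origin_lat - (row+1)*res, origin_lat - row*res]`` in latitude, so a
    point on a shared edge belongs to exactly one cell.
    """

    shape: tuple[int, int]
    resolution_deg: float = 0.05
    origin: tuple[float, float] = (-180.0, 90.0)
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if self.resolution_deg <= 0:
            raise ValueError("resolution_deg must be > 0")

    @property
    def rows(self) -> int:
        return self.shape[0]

    @property
    def cols(self) -> int:
        return self.shape[1]

    def cell_of(self, lon, lat):
        """Map lon/lat arrays to (row, col) arrays (may fall outside grid)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin[0]) / self.resolution_deg).astype(int)
        row = np.floor((self.origin[1] - lat) / self.resolution_deg).astype(int)
        return row, col

    def inside(self, row, col):
        return (row >= 0) & (row < self.rows) & (col >= 0) & (col < self.cols)

    def cell_center(self, row, col):
        lon = self.origin[0] + (np.asarray(col) + 0.5) * self.resolution_deg
        lat = self.origin[1] - (np.asarray(row) + 0.5) * self.resolution_deg
        return lon, lat

    def lat_edges(self, row):
        """(north_edge, south_edge) latitudes of a row."""
        north = self.origin[1] - np.asarray(row) * self.resolution_deg
        return north, north - self.resolution_deg

    def center_lats(self) -> np.ndarray:
        """Latitude of every row center, length ``rows``."""
        return self.origin[1] - (np.arange(self.rows) + 0.5) * self.resolution_deg

    def __eq__(self, other) -> bool:  # tolerant float comparison
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.shape == other.shape
            and math.isclose(self.resolution_deg, other.resolution_deg, rel_tol=1e-12)
            and math.isclose(self.origin[0], other.origin[0], abs_tol=1e-9)
            and math.isclose(self.origin[1], other.origin[1], abs_tol=1e-9)
            and self.crs == other.crs
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass
class Raster:
    """A single named layer on a :class:`GridSpec`.

    ``values`` is float (NoData = NaN or sentinel) or integer (NoData =
    sentinel, default -9999) for categorical layers.
    """

    values: np.ndarray
    grid: GridSpec
    name: str = "layer"
    nodata: float = float("nan")
    categorical: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells carrying data."""
        if isinstance(self.nodata, float) and math.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Raster":
        return Raster(values, self.grid, name or self.name, self.nodata, self.categorical)

    def write_ascii(self, path: str | Path) -> Path:
        """Write as Arc/Info ASCII grid + ``.json`` metadata sidecar."""
        path = Path(path)
        g = self.grid
        xll = g.origin[0]
        yll = g.origin[1] - g.rows * g.resolution_deg
        nodata = -9999 if (isinstance(self.nodata, float) and math.isnan(self.nodata)) else self.nodata
        vals = self.values
        if isinstance(self.nodata, float) and math.isnan(self.nodata):
            vals = np.where(np.isnan(vals), float(nodata), vals)
        fmt = "%d" if np.issubdtype(self.values.dtype, np.integer) else "%.10g"
        with open(path, "w") as fh:
            fh.write(
                f"ncols {g.cols}\nnrows {g.rows}\n"
                f"xllcorner {xll:.10g}\nyllcorner {yll:.10g}\n"
                f"cellsize {g.resolution_deg:.10g}\nNODATA_value {nodata}\n"
            )
            np.savetxt(fh, vals, fmt=fmt)
        meta = {"name": self.name, "crs": g.crs, "categorical": self.categorical}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
        return path


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an Arc/Info ASCII grid written by :meth:`Raster.write_ascii`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(rows, cols)
    grid = GridSpec(
        shape=(rows, cols),
        resolution_deg=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"] + rows * header["cellsize"]),
    )
    name, categorical = path.stem, False
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        name = meta.get("name", name)
        categorical = bool(meta.get("categorical", False))
    nodata = header["nodata_value"]
    if categorical:
        values: np.ndarray = data.astype(int)
        nodata = int(nodata)
    else:
        values = np.where(data == nodata, np.nan, data)
        nodata = float("nan")
    return Raster(values, grid, name=name, nodata=nodata, categorical=categorical)


class EnvStack:
    """Named multi-layer raster stack on one shared grid."""

    def __init__(self, layers: dict[str, Raster] | list[Raster]):
        if isinstance(layers, list):
            layers = {r.name: r for r in layers}
        if not layers:
            raise ValueError("empty stack")
        self.layers: dict[str, Raster] = dict(layers)
        grids = list(r.grid for r in self.layers.values())
        self.grid = grids[0]
        for r in self.layers.values():
            if r.grid != self.grid:
                raise ValueError(f"layer {r.name!r} is on a different grid")

    def __getitem__(self, name: str) -> Raster:
        if name not in self.layers:
            raise KeyError(f"unknown layer {name!r}; stack has {sorted(self.layers)}")
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def valid(self) -> np.ndarray:
        """Cells valid in *every* layer."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for r in self.layers.values():
            mask &= r.valid
        return mask

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        return {name: r.write_ascii(directory / f"{name}.asc") for name, r in self.layers.items()}

    @classmethod
    def read(cls, directory: str | Path) -> "EnvStack":
        paths = sorted(Path(directory).glob("*.asc"))
        if not paths:
            raise FileNotFoundError(f"no .asc layers under {directory}")
        return cls([read_ascii_grid(p) for p in paths])
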