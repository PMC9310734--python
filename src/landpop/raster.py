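"""Single-band georeferenced raster grid in WGS84 lon/lat.

Conventions: row 0 is the northmost row; cell centers sit at
``(west + (col + 0.5) * dx, north - (row + 0.5) * dy)``; cells are
square-ish (dx ~ dy). Nodata cells are carried as a boolean mask and
serialized with a sentinel value in Esri ASCII grid files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

_DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    values: np.ndarray            # (rows, cols) float array, NaN allowed at masked cells
    west: float                   # longitude of the west edge, degrees
    north: float                  # latitude of the north edge, degrees
    cell_size: float              # degrees per cell (dx == dy)
    nodata_mask: np.ndarray | None = None   # True where the cell carries no data
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.isnan(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata mask shape mismatch")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def south(self) -> float:
        return self.north - self.shape[0] * self.cell_size

    @property
    def east(self) -> float:
        return self.west + self.shape[1] * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) in degrees."""
        return (self.west, self.south, self.east, self.north)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.west + (col + 0.5) * self.cell_size
        lat = self.north - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of lon and lat of every cell center, shaped like the grid."""
        rows, cols = self.shape
        lon = self.west + (np.arange(cols) + 0.5) * self.cell_size
        lat = self.north - (np.arange(rows) + 0.5) * self.cell_size
        return np.broadcast_to(lon, (rows, cols)).copy(), np.broadcast_to(
            lat[:, None], (rows, cols)
        ).copy()

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (south/west edge owned by the cell)."""
        col = int(np.floor((lon - self.west) / self.cell_size))
        row = int(np.floor((self.north - lat) / self.cell_size))
        rows, cols = self.shape
        if not (0 <= row < rows and 0 <= col < cols):
            raise ValueError(f"point ({lon}, {lat}) outside raster extent {self.extent}")
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        return (self.west <= lon < self.east) and (self.south < lat <= self.north)

    # -- algebra ------------------------------------------------------------

    def aligned_with(self, other: "Raster", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.west - other.west) <= tol
            and abs(self.north - other.north) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def with_values(self, values: np.ndarray, name: str = "") -> "Raster":
        """New raster on the same grid, union-ing the nodata mask with new NaNs."""
        values = np.asarray(values, dtype=float)
        mask = self.nodata_mask | np.isnan(values)
        out = values.copy()
        out[mask] = np.nan
        return Raster(out, self.west, self.north, self.cell_size, mask, name or self.name)

    def masked_values(self) -> np.ndarray:
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out


def require_aligned(*rasters: Raster) -> None:
    first = rasters[0]
    for r in rasters[1:]:
        if not first.aligned_with(r):
            raise ValueError("rasters are not grid-aligned (shape/extent/cell size differ)")


# -- Esri ASCII grid I/O ----------------------------------------------------

def read_ascii_grid(path: str | Path, name: str = "") -> Raster:
    """Read an Esri ASCII grid (.asc). Supports xllcorner/yllcorner and cell-center keys."""
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            } and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    try:
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        cell = header["cellsize"]
    except KeyError as exc:
        raise ValueError(f"{path}: missing required AAIGrid header key {exc}") from exc
    if "xllcorner" in header:
        west = header["xllcorner"]
    elif "xllcenter" in header:
        west = header["xllcenter"] - cell / 2
    else:
        raise ValueError(f"{path}: no x origin in header")
    if "yllcorner" in header:
        south = header["yllcorner"]
    elif "yllcenter" in header:
        south = header["yllcenter"] - cell / 2
    else:
        raise ValueError(f"{path}: no y origin in header")
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    values = np.array(" ".join(data_lines).split(), dtype=float)
    if values.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows * ncols} cells, found {values.size}"
        )
    values = values.reshape(nrows, ncols)
    mask = values == nodata
    values = values.astype(float)
    values[mask] = np.nan
    return Raster(values, west, south + nrows * cell, cell, mask, name or path.stem)


def write_ascii_grid(raster: Raster, path: str | Path, nodata: float = _DEFAULT_NODATA) -> None:
    path = Path(path)
    nrows, ncols = raster.shape
    values = raster.values.copy()
    values[raster.nodata_mask] = nodata
    values[np.isnan(values)] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(raster.west)!r}\n")
        fh.write(f"yllcorner {float(raster.south)!r}\n")
        fh.write(f"cellsize {float(raster.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for row in values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
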