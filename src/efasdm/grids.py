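"""Planar raster grids and the plain-text raster formats the pipeline reads and writes.

All spatial stages share a single currency: :class:`RasterGrid`, a georeferenced
2-D array on a planar (km-based) coordinate system with an optional nodata mask
(NaN cells).  Rasters are serialised as ESRI ASCII grids (``.asc``) so every
artefact in a run directory is human-readable text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RasterGrid",
    "SatelliteSeries",
    "read_ascii_grid",
    "write_ascii_grid",
]

_NODATA = -9999.0


@dataclass(frozen=True)
class RasterGrid:
    """A 2-D raster on a planar grid.

    Parameters
    ----------
    data
        2-D float array; NaN marks nodata.  Row 0 is the *northern* edge.
    cell_size
        Cell edge length in km.
    x0, y0
        Coordinates (km) of the lower-left corner of the grid.
    """

    data: np.ndarray
    cell_size: float = 1.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {arr.shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "data", arr)

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.data).sum())

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size ** 2

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
        )

    def require_same_grid(self, other: "RasterGrid") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch: {self.shape}@{self.cell_size}km vs "
                f"{other.shape}@{other.cell_size}km"
            )

    # -- coordinate helpers ---------------------------------------------
    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) km of the center of cell (row, col); row 0 is the top."""
        nrows = self.shape[0]
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 + (nrows - row - 0.5) * self.cell_size
        return x, y

    def cell_of_point(self, x: float, y: float) -> tuple[int, int] | None:
        """Grid cell containing (x, y), or None if outside the extent."""
        nrows, ncols = self.shape
        col = int(np.floor((x - self.x0) / self.cell_size))
        row_from_bottom = int(np.floor((y - self.y0) / self.cell_size))
        row = nrows - 1 - row_from_bottom
        if 0 <= row < nrows and 0 <= col < ncols:
            return row, col
        return None

    # -- derivation ------------------------------------------------------
    def with_data(self, data: np.ndarray) -> "RasterGrid":
        return replace(self, data=np.asarray(data, dtype=float))

    def window(self, row0: int, col0: int, nrows: int, ncols: int) -> "RasterGrid":
        """Rectangular sub-raster (a nested extent)."""
        if row0 < 0 or col0 < 0 or row0 + nrows > self.shape[0] or col0 + ncols > self.shape[1]:
            raise ValueError("window exceeds raster bounds")
        sub = self.data[row0 : row0 + nrows, col0 : col0 + ncols].copy()
        x0 = self.x0 + col0 * self.cell_size
        y0 = self.y0 + (self.shape[0] - row0 - nrows) * self.cell_size
        return RasterGrid(sub, cell_size=self.cell_size, x0=x0, y0=y0)


@dataclass
class SatelliteSeries:
    """A dated stack of composite rasters for one satellite dimension.

    ``dimension`` is one of ``"EVI"``, ``"LST"``, ``"ALB"``.  Composites are
    (year, day_of_year, raster) triples, strictly ordered in time, with at
    least 12 composites per covered year.
    """

    dimension: str
    composites: list[tuple[int, int, RasterGrid]] = field(default_factory=list)

    VALID_DIMENSIONS = ("EVI", "LST", "ALB")

    def __post_init__(self) -> None:
        if self.dimension not in self.VALID_DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        keys = [(y, d) for y, d, _ in self.composites]
        if keys != sorted(keys) or len(set(keys)) != len(keys):
            raise ValueError("composites must be strictly ordered by (year, day_of_year)")

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _, _ in self.composites})

    def year_slice(self, year: int) -> list[tuple[int, RasterGrid]]:
        out = [(d, g) for y, d, g in self.composites if y == year]
        if len(out) < 12:
            raise ValueError(
                f"{self.dimension}: year {year} has {len(out)} composites, need >= 12"
            )
        return out

    def grid(self) -> RasterGrid:
        return self.composites[0][2]

    def as_array(self, year: int) -> tuple[np.ndarray, np.ndarray]:
        """(days, cube) for one year: days (n,), cube (n, rows, cols)."""
        pairs = self.year_slice(year)
        days = np.array([d for d, _ in pairs])
        cube = np.stack([g.data for _, g in pairs])
        return days, cube


# ---------------------------------------------------------------------------
# Plain-text raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: RasterGrid, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid (cell size stored in km)."""
    path = Path(path)
    nrows, ncols = grid.shape
    data = np.where(np.isfinite(grid.data), grid.data, _NODATA)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.x0:.6f}\n"
        f"yllcorner {grid.y0:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {_NODATA:.1f}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in data)
    path.write_text(header + body + "\n")
    return path


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    lines = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            hdr[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    data = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    nodata = hdr.get("nodata_value", _NODATA)
    data = np.where(np.isclose(data, nodata), np.nan, data)
    if data.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
        raise ValueError(f"{path}: body shape {data.shape} disagrees with header")
    return RasterGrid(
        data,
        cell_size=hdr.get("cellsize", 1.0),
        x0=hdr.get("xllcorner", 0.0),
        y0=hdr.get("yllcorner", 0.0),
    )
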