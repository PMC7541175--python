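"""Georeferenced single-band raster grid.

A :class:`Grid` is a 2-D array of cell values on a square metric lattice.
Row 0 is the northernmost row; ``origin_x``/``origin_y`` give the *outer*
(north-west) corner of cell ``[0, 0]``, so the centre of cell ``(r, c)`` sits
at ``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``.
Extents are half-open. Missing cells are carried as NaN plus an explicit
nodata mask.

Grids round-trip through the plain-text ESRI ASCII grid format
(``read_ascii_grid`` / ``write_ascii_grid``); an optional sidecar carries the
CRS tag, since the .asc header has no CRS slot. All layers of one analysis
must share a single projected metric CRS — mixed CRSs are refused, never
silently reprojected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Grid", "GridError", "read_ascii_grid", "write_ascii_grid"]


class GridError(ValueError):
    """Invalid grid construction or incompatible georeferencing."""


@dataclass
class Grid:
    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    crs_tag: str = ""
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise GridError("grid values must be a 2-D array with >=1 row and column")
        if not self.cell_size > 0:
            raise GridError(f"cell_size must be > 0, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = np.isnan(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise GridError("nodata_mask shape mismatch")
            self.values = np.where(self.nodata_mask, np.nan, self.values)

    # -- georeferencing -----------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_center(self, row, col):
        """World coordinates of cell centres (vectorised)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (x, y) of all cell-centre coordinates."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def world_to_cell(self, x, y):
        """Row/col indices of the cells containing points (half-open cells)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y):
        """Boolean: points inside the half-open grid extent."""
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def sample_nearest(self, x, y):
        """Nearest-cell values at world points; NaN outside the extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)
        row, col = self.world_to_cell(x, y)
        out = np.full(np.broadcast(x, y).shape, np.nan)
        r = np.clip(row, 0, self.n_rows - 1)
        c = np.clip(col, 0, self.n_cols - 1)
        out = np.where(inside, self.values[r, c], np.nan)
        return out

    def same_georeference(self, other: "Grid", atol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.origin_x - other.origin_x) <= atol
            and abs(self.origin_y - other.origin_y) <= atol
            and abs(self.cell_size - other.cell_size) <= atol
            and self.crs_tag == other.crs_tag
        )

    def require_same_georeference(self, other: "Grid", what: str = "grid") -> None:
        if self.crs_tag != other.crs_tag:
            raise GridError(
                f"CRS mismatch for {what}: {self.crs_tag!r} vs {other.crs_tag!r}; "
                "reproject inputs to one metric CRS first"
            )
        if not self.same_georeference(other):
            raise GridError(f"georeferencing mismatch for {what}")

    def like(self, values: np.ndarray) -> "Grid":
        """New grid with this georeferencing and the given values."""
        return Grid(
            values=np.asarray(values, dtype=float),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            crs_tag=self.crs_tag,
        )

    def full_like(self, fill: float = np.nan) -> "Grid":
        return self.like(np.full(self.values.shape, fill))


# -- plain-text I/O ---------------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc); CRS tag goes to a ``.crs`` sidecar."""
    path = Path(path)
    vals = np.where(grid.nodata_mask, _NODATA, grid.values)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")
    if grid.crs_tag:
        Path(str(path) + ".crs").write_text(grid.crs_tag + "\n")


def read_ascii_grid(path: str | Path) -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        values = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridError(f"{path}: missing ASCII-grid header field {key}")
    nodata = header.get("nodata_value", _NODATA)
    values = np.where(values == nodata, np.nan, values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise GridError(f"{path}: data shape does not match header")
    cell = header["cellsize"]
    crs_path = Path(str(path) + ".crs")
    crs = crs_path.read_text().strip() if crs_path.exists() else ""
    if "xllcorner" in header:
        x0 = header["xllcorner"]
        y0 = header["yllcorner"] + values.shape[0] * cell
    else:  # xllcenter variant
        x0 = header["xllcenter"] - cell / 2
        y0 = header["yllcenter"] - cell / 2 + values.shape[0] * cell
    return Grid(values=values, origin_x=x0, origin_y=y0, cell_size=cell, crs_tag=crs)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
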