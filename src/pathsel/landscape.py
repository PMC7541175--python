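"""Raster transforms for the landscape layers.

Distance-to-feature grids, the log-flatten transform that caps the influence
of a linear disturbance beyond a fixed range, slope from a DEM, and
along-polyline raster sampling.

The flatten rule encodes that proximity to a road/fence/berm only matters
within a short range: cells further than ``flatten_distance`` (default 60 m)
all receive the same plateau value ``ln(flatten_distance + offset)``, while
the gradient below the threshold is preserved on the natural-log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiLineString

from .features import LinearFeature
from .grid import Grid, GridError

__all__ = [
    "DistanceTransformConfig",
    "distance_grid",
    "log_flatten",
    "slope_from_dem",
    "sample_along_polyline",
    "polyline_stations",
]


@dataclass
class DistanceTransformConfig:
    """Log-flatten parameters: cap at ``flatten_distance``; ``offset`` is
    added before the log so on-feature cells (d = 0) stay finite."""

    flatten_distance: float = 60.0
    offset: float = 1.0

    def __post_init__(self) -> None:
        if not self.flatten_distance > 0:
            raise ValueError("flatten_distance must be > 0")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")

    @property
    def plateau(self) -> float:
        """Transformed value for any distance at or beyond the cap."""
        return float(np.log(self.flatten_distance + self.offset))


def distance_grid(
    features: list[LinearFeature], template: Grid, which_type: str
) -> Grid:
    """Euclidean distance (m) from each cell centre to the nearest polyline
    of ``which_type``. With no such feature an all-missing grid is returned
    and a warning issued (no feature of that kind in the landscape)."""
    lines = [f.geometry for f in features if f.feature_type == which_type]
    if not lines:
        warnings.warn(
            f"no features of type {which_type!r}; returning all-missing distance grid",
            stacklevel=2,
        )
        return template.full_like(np.nan)
    target = MultiLineString(lines)
    x, y = template.cell_centers()
    pts = shapely.points(x.ravel(), y.ravel())
    d = shapely.distance(pts, target).reshape(template.values.shape)
    return template.like(d)


def log_flatten(distances: Grid, cfg: DistanceTransformConfig | None = None) -> Grid:
    cfg = cfg or DistanceTransformConfig()
    vals = distances.values
    with np.errstate(invalid="ignore"):
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("distances must be >= 0")
        out = np.log(np.minimum(vals, cfg.flatten_distance) + cfg.offset)
    return distances.like(out)


def slope_from_dem(dem: Grid) -> Grid:
    """Slope in degrees via the Horn 3x3 finite-difference estimator.

    Edge cells use one-sided differences (via linear edge extrapolation, which
    makes the centred stencil equal the one-sided one)."""
    if dem.n_rows < 2 or dem.n_cols < 2:
        raise GridError("slope needs a DEM of at least 2x2 cells")
    z = dem.values
    # linear extrapolation pad: centred difference at the edge == one-sided
    zp = np.pad(z, 1, mode="edge")
    zp[0, :] = 2 * zp[1, :] - zp[2, :]
    zp[-1, :] = 2 * zp[-2, :] - zp[-3, :]
    zp[:, 0] = 2 * zp[:, 1] - zp[:, 2]
    zp[:, -1] = 2 * zp[:, -2] - zp[:, -3]
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                   f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * dem.cell_size)
    dz_dy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * dem.cell_size)
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    return dem.like(slope)


def polyline_stations(polyline: np.ndarray, spacing: float) -> np.ndarray:
    """Evenly spaced arc-length stations at most ``spacing`` m apart, always
    including the first and last vertex; the even spacing makes the station
    set mirror-symmetric under path reversal. Zero-length lines yield one
    point."""
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be an (n, 2) array")
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1]) if len(seg) else np.array([])
    total = float(seglen.sum()) if len(seglen) else 0.0
    if total == 0.0:
        return pts[:1].copy()
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    n_seg = max(1, int(np.ceil(total / spacing - 1e-9)))
    s = np.linspace(0.0, total, n_seg + 1)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return np.column_stack([x, y])


def sample_along_polyline(grid: Grid, polyline: np.ndarray, spacing: float) -> np.ndarray:
    """Nearest-cell grid values at arc-length stations along the polyline.
    Stations outside the grid extent sample as NaN (missing)."""
    stations = polyline_stations(polyline, spacing)
    return grid.sample_nearest(stations[:, 0], stations[:, 1])
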