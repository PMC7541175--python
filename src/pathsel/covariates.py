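"""Path-mean covariates, feature encounters, NA-gating, standardization.

Each path (observed or random) is reduced to one row: the mean of each
raster covariate sampled densely along the path.  Anthropogenic covariates
(road/fence/floodcontrol/rail distance) are *gated*: an animal whose home
range never intersects a feature is uninformed about it, so that covariate
is set missing for every one of the animal's paths — gating is per animal,
hence identical across all rows of a stratum.  Missing values are carried as
NaN and, after standardization, contribute zero to any linear predictor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage import measure

from .features import FEATURE_TYPES, LinearFeature
from .grid import Grid
from .landscape import polyline_stations, sample_along_polyline
from .paths import Path
from .randomwalk import RandomPathSet

__all__ = [
    "extract_path_means",
    "build_design",
    "encounters",
    "gate_features",
    "kde_isopleth_95",
    "standardize",
    "destandardize",
]


def extract_path_means(
    path: Path, grids: dict[str, Grid], spacing: float | None = None
) -> dict[str, float]:
    """Unweighted mean of nearest-cell samples every ``spacing`` m along the
    path (default: cell_size / 3).  Missing cells are excluded from the
    mean; a path entirely off a grid yields a missing covariate."""
    out: dict[str, float] = {}
    stations_by_spacing: dict[float, np.ndarray] = {}
    for name, grid in grids.items():
        sp = spacing if spacing is not None else grid.cell_size / 3.0
        if sp not in stations_by_spacing:
            stations_by_spacing[sp] = polyline_stations(path.coords, sp)
        st = stations_by_spacing[sp]
        vals = grid.sample_nearest(st[:, 0], st[:, 1])
        good = ~np.isnan(vals)
        if not good.any():
            warnings.warn(f"path {path.path_id} entirely outside grid {name!r}", stacklevel=2)
            out[name] = np.nan
        else:
            out[name] = float(vals[good].mean())
    return out


def build_design(
    path_sets: list[RandomPathSet],
    grids: dict[str, Grid],
    spacing: float | None = None,
) -> pd.DataFrame:
    """One row per path across all strata: stratum_id, animal_id, role,
    then one column per covariate grid."""
    rows = []
    for ps in path_sets:
        for p in ps.all_paths:
            rows.append(
                {
                    "stratum_id": ps.stratum_id,
                    "animal_id": p.animal_id,
                    "role": "observed" if p.is_observed else "random",
                    **extract_path_means(p, grids, spacing),
                }
            )
    return pd.DataFrame(rows)


def encounters(
    home_ranges: dict[str, "Polygon"], features: list[LinearFeature]
) -> pd.DataFrame:
    """Animal x feature-type boolean table: does any polyline of the type
    intersect the animal's home-range polygon (boundary contact counts)."""
    by_type = {t: [f.geometry for f in features if f.feature_type == t] for t in FEATURE_TYPES}
    merged = {t: unary_union(gs) if gs else None for t, gs in by_type.items()}
    rows = {}
    for animal, poly in home_ranges.items():
        rows[animal] = {
            t: bool(merged[t] is not None and merged[t].intersects(poly))
            for t in FEATURE_TYPES
        }
    tab = pd.DataFrame.from_dict(rows, orient="index")
    tab.index.name = "animal_id"
    return tab


def gate_features(table: pd.DataFrame, enc: pd.DataFrame) -> pd.DataFrame:
    """Set anthropogenic covariates to missing for animals that never
    encountered the feature; natural covariates are never gated."""
    out = table.copy()
    for ftype in FEATURE_TYPES:
        if ftype not in out.columns:
            continue
        for animal in out["animal_id"].unique():
            if animal in enc.index and not bool(enc.loc[animal, ftype]):
                out.loc[out["animal_id"] == animal, ftype] = np.nan
    return out


def kde_isopleth_95(
    fixes_xy: np.ndarray,
    bandwidth_rule: str = "scott",
    level: float = 0.95,
    grid_n: int = 128,
    pad_factor: float = 0.3,
):
    """95% density isopleth of a plain Gaussian KDE over fixes.

    This is a convenience fallback for supplying encounter polygons when no
    externally estimated home ranges are available.  It is a *plain* kernel
    density with a plug-in bandwidth — NOT an autocorrelated (movement-model
    conditioned) home-range estimator — and is labelled as such in the
    returned metadata.

    Returns (geometry, metadata): a shapely (Multi)Polygon plus a dict.
    """
    pts = np.asarray(fixes_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise ValueError("need >= 5 (x, y) fixes for a density isopleth")
    if np.ptp(pts[:, 0]) == 0 or np.ptp(pts[:, 1]) == 0:
        raise ValueError("degenerate fix cloud (zero spatial extent)")
    kde = gaussian_kde(pts.T, bw_method=bandwidth_rule)
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    padx = (xmax - xmin) * pad_factor
    pady = (ymax - ymin) * pad_factor
    xs = np.linspace(xmin - padx, xmax + padx, grid_n)
    ys = np.linspace(ymin - pady, ymax + pady, grid_n)
    xx, yy = np.meshgrid(xs, ys)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    # density threshold enclosing `level` of the estimated mass
    flat = np.sort(dens.ravel())[::-1]
    csum = np.cumsum(flat)
    csum /= csum[-1]
    thr = flat[np.searchsorted(csum, level)]
    polys = []
    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]
    for contour in measure.find_contours(dens, thr):
        if len(contour) < 4:
            continue
        world = np.column_stack(
            [xs[0] + contour[:, 1] * dx, ys[0] + contour[:, 0] * dy]
        )
        poly = Polygon(world)
        if poly.is_valid and poly.area > 0:
            polys.append(poly)
    geom = unary_union(polys)
    meta = {
        "method": "plain Gaussian KDE isopleth (not AKDE)",
        "level": level,
        "bandwidth_rule": bandwidth_rule,
        "n_fixes": len(pts),
        "n_parts": len(polys),
    }
    return geom, meta


def standardize(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score the named covariate columns over ALL rows (observed and
    random pooled), ignoring missing entries.  Returns the transformed table
    and per-column (mean, sd) for prediction-time reuse."""
    out = table.copy()
    transform: dict[str, tuple[float, float]] = {}
    for col in columns:
        v = out[col].to_numpy(dtype=float)
        good = ~np.isnan(v)
        if not good.any():
            transform[col] = (0.0, 1.0)
            continue
        m = float(v[good].mean())
        s = float(v[good].std(ddof=0))
        if s == 0:
            raise ValueError(f"covariate column {col!r} is constant; cannot standardize")
        out[col] = (v - m) / s
        transform[col] = (m, s)
    return out, transform


def destandardize(
    table: pd.DataFrame, transform: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    out = table.copy()
    for col, (m, s) in transform.items():
        if col in out.columns:
            out[col] = out[col].to_numpy(dtype=float) * s + m
    return out
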