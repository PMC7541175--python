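"""Landscape movement-quality (resistance) surfaces from a fitted model.

The fitted selection coefficients are pushed back over the covariate rasters
to score every cell: eta(cell) = sum_p beta_p x_p(cell) on the standardized
scale used in fitting, with quadratics and interactions recomputed from the
standardized cell values.  Linear-barrier distance covariates are *held
constant* (default: at the far log-flatten plateau), so the attraction of
animals to fences/berms does not masquerade as high-quality movement
habitat.  The surface is then classified into n empirical quantiles (the
Movement Quality Index) and into Fisher–Jenks natural-break classes for
display, and contiguous top-class patches are extracted as candidate
corridors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .grid import Grid
from .landscape import DistanceTransformConfig
from .model import FittedModel, _term_parents

__all__ = [
    "PredictionConfig",
    "MovementSurface",
    "predict_surface",
    "fisher_breaks",
    "classify_breaks",
    "quantile_classes",
    "corridor_patches",
]

DEFAULT_HELD = ("fence", "floodcontrol", "rail")


@dataclass
class PredictionConfig:
    """Held-constant barrier values are given on the log-flattened scale
    (default: the far plateau ln(61)) and standardized with the fit-time
    transform before entering the predictor."""

    hold_covariates: tuple[str, ...] = DEFAULT_HELD
    barrier_hold: dict[str, float] = field(default_factory=dict)
    n_quantiles: int = 10
    n_fisher_classes: int = 7
    habitat_mask: Grid | None = None
    fisher_max_sample: int = 3000

    def __post_init__(self) -> None:
        if self.n_quantiles < 2:
            raise ValueError("n_quantiles must be >= 2")
        plateau = DistanceTransformConfig().plateau
        for name in self.hold_covariates:
            self.barrier_hold.setdefault(name, plateau)


@dataclass
class MovementSurface:
    linear_predictor: Grid
    relative_quality: Grid
    mqi: Grid
    fisher_classes: Grid
    fisher_break_values: np.ndarray


def predict_surface(
    fitted: FittedModel,
    grids: dict[str, Grid],
    transform: dict[str, tuple[float, float]],
    cfg: PredictionConfig | None = None,
) -> MovementSurface:
    """Per-cell linear predictor, relative quality exp(eta - max eta), MQI
    quantile classes, and Fisher-break classes for a fitted model."""
    cfg = cfg or PredictionConfig()
    linear_terms = sorted({p for t in fitted.terms for p in _term_parents(t)})
    z: dict[str, np.ndarray] = {}
    template: Grid | None = None
    for name in linear_terms:
        m, s = transform.get(name, (0.0, 1.0))
        if name in cfg.hold_covariates:
            continue  # resolved below against the template shape
        if name not in grids:
            raise ValueError(f"no covariate grid supplied for fitted term {name!r}")
        g = grids[name]
        if template is None:
            template = g
        else:
            template.require_same_georeference(g, name)
        z[name] = (g.values - m) / s
    if template is None:
        template = next(iter(grids.values()))
    shape = template.values.shape
    for name in linear_terms:
        if name in cfg.hold_covariates:
            m, s = transform.get(name, (0.0, 1.0))
            z[name] = np.full(shape, (cfg.barrier_hold[name] - m) / s)
    eta = np.zeros(shape)
    for term, b in zip(fitted.terms, fitted.beta):
        if ":" in term:
            a, c = term.split(":")
            val = z[a] * z[c]
        elif term.endswith("^2"):
            val = z[term[:-2]] ** 2
        else:
            val = z[term]
        eta = eta + b * val
    mask = np.isnan(eta)
    if cfg.habitat_mask is not None:
        hm = cfg.habitat_mask.values
        mask |= np.isnan(hm) | (hm == 0)
        eta = np.where(mask, np.nan, eta)
    lp = template.like(eta)
    rel = template.like(np.exp(eta - np.nanmax(eta)) if not np.all(mask) else eta)
    mqi = quantile_classes(lp, cfg.n_quantiles)
    vals = eta[~np.isnan(eta)]
    if vals.size == 0:
        breaks = np.array([])
        fisher = template.like(np.full(shape, np.nan))
    elif np.ptp(vals) == 0:
        warnings.warn("constant prediction surface; single display class", stacklevel=2)
        breaks = np.array([])
        fisher = template.like(np.where(np.isnan(eta), np.nan, 1.0))
    else:
        sample = vals
        if len(sample) > cfg.fisher_max_sample:
            rng = np.random.default_rng(0)
            sample = rng.choice(vals, cfg.fisher_max_sample, replace=False)
        k = min(cfg.n_fisher_classes, len(np.unique(sample)))
        breaks = fisher_breaks(sample, k)
        fisher = template.like(classify_breaks(eta, breaks).astype(float))
        fisher.values[np.isnan(eta)] = np.nan
    return MovementSurface(
        linear_predictor=lp, relative_quality=rel, mqi=mqi,
        fisher_classes=fisher, fisher_break_values=breaks,
    )


def fisher_breaks(values: np.ndarray, k: int) -> np.ndarray:
    """Exact Fisher–Jenks k-class breaks (dynamic program minimizing total
    within-class sum of squared deviations).  Returns the k-1 interior break
    values: the maximum of each class but the last."""
    v = np.sort(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    n = len(v)
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def sse_vec(i: np.ndarray, j: int) -> np.ndarray:
        cnt = j - i + 1
        tot = s1[j + 1] - s1[i]
        return (s2[j + 1] - s2[i]) - tot * tot / cnt

    D = np.full((k, n), np.inf)
    back = np.zeros((k, n), dtype=int)
    j_all = np.arange(n)
    D[0, :] = (s2[1:] - s1[1:] ** 2 / (j_all + 1))
    for c in range(1, k):
        for j in range(c, n):
            i = np.arange(c, j + 1)
            cand = D[c - 1, i - 1] + sse_vec(i, j)
            a = int(np.argmin(cand))
            D[c, j] = cand[a]
            back[c, j] = i[a]
    cuts = []
    j = n - 1
    for c in range(k - 1, 0, -1):
        i = back[c, j]
        cuts.append(v[i - 1])  # max of the class below the cut
        j = i - 1
    return np.array(cuts[::-1])


def classify_breaks(values: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Class indices 1..k for given interior break values (class maxima)."""
    return np.searchsorted(breaks, values, side="left") + 1


def quantile_classes(grid: Grid, n: int, mask: Grid | None = None) -> Grid:
    """Empirical n-quantile classes (1..n) over unmasked cells; ties go to
    the lower class; masked/missing cells stay missing."""
    vals = grid.values.copy()
    if mask is not None:
        mv = mask.values
        vals = np.where(np.isnan(mv) | (mv == 0), np.nan, vals)
    good = ~np.isnan(vals)
    flat = vals[good]
    out = np.full(vals.shape, np.nan)
    if flat.size == 0:
        return grid.like(out)
    if np.ptp(flat) == 0:
        warnings.warn("constant grid: single quantile class", stacklevel=2)
        out[good] = 1
        return grid.like(out)
    order = np.sort(flat)
    # rank = number of values strictly below; ties share the lower class
    rank = np.searchsorted(order, flat, side="left")
    cls = np.minimum(n, (rank * n) // flat.size + 1)
    out[good] = cls
    return grid.like(out)


def corridor_patches(
    mqi: Grid, min_class: int, connectivity: int = 8
) -> "pd.DataFrame":
    """Connected components of cells with class >= min_class.

    Per patch: area (ha), bounding-box length (m, long side), minimum width
    (m, 2x the maximum internal distance-transform value on the patch
    skeleton), and centroid world coordinates.
    """
    import pandas as pd

    qual = np.nan_to_num(mqi.values, nan=-np.inf) >= min_class
    structure = (
        np.ones((3, 3), dtype=int) if connectivity == 8
        else np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    labels, n_patch = ndimage.label(qual, structure=structure)
    cell = mqi.cell_size
    recs = []
    for lab in range(1, n_patch + 1):
        patch = labels == lab
        count = int(patch.sum())
        rows, cols = np.nonzero(patch)
        bbox_h = (rows.max() - rows.min() + 1) * cell
        bbox_w = (cols.max() - cols.min() + 1) * cell
        edt = ndimage.distance_transform_edt(patch) * cell
        skel = skeletonize(patch)
        on_skel = edt[skel] if skel.any() else edt[patch]
        cx, cy = mqi.cell_center(rows.mean(), cols.mean())
        recs.append(
            {
                "patch_id": lab,
                "n_cells": count,
                "area_ha": count * cell * cell / 1e4,
                "bbox_length_m": float(max(bbox_h, bbox_w)),
                "bbox_width_m": float(min(bbox_h, bbox_w)),
                "min_width_m": float(2 * on_skel.max()),
                "centroid_x": float(cx),
                "centroid_y": float(cy),
            }
        )
    return pd.DataFrame(recs)
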