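"""End-to-end orchestration: clean -> segment -> distributions -> random
paths -> extract -> gate -> standardize -> fit (-> predict).

`run_path_selection` is the library entry point used by the tests, the
acceptance script, the analysis drivers and the CLI; `run_pipeline` wraps it
with file I/O and a reproducibility manifest.  All randomness flows from one
top-level seed; derived per-stage seeds are recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from .cleaning import CleaningConfig, clean_telemetry
from .covariates import build_design, encounters, gate_features, kde_isopleth_95, standardize
from .features import FEATURE_TYPES, LinearFeature
from .grid import Grid
from .model import FittedModel, ModelSpec, StratumData, fit_fixed, fit_random_slopes
from .paths import PathConfig, eligible_animals, segment_paths, step_stats
from .randomwalk import generate_random_paths

__all__ = ["PipelineResult", "run_path_selection", "run_pipeline"]

COVARIATE_NAMES = ["slope", "wash", "veg", "habitat", "road", "fence", "floodcontrol", "rail"]


@dataclass
class PipelineResult:
    fitted: FittedModel
    strata: StratumData
    design: pd.DataFrame
    transform: dict[str, tuple[float, float]]
    dists: object
    path_sets: list
    kept_fixes: pd.DataFrame
    removal_report: pd.DataFrame
    encounter_table: pd.DataFrame | None
    spec: ModelSpec
    counts: dict = field(default_factory=dict)


def _home_range_polygons(kept: pd.DataFrame, seed: int, max_fixes: int = 400):
    polys = {}
    rng = np.random.default_rng(seed)
    for animal, grp in kept.groupby("animal_id", sort=False):
        pts = grp[["x", "y"]].to_numpy()
        if len(pts) > max_fixes:
            pts = pts[rng.choice(len(pts), max_fixes, replace=False)]
        try:
            geom, _meta = kde_isopleth_95(pts)
            polys[str(animal)] = geom
        except ValueError:
            continue
    return polys


def run_path_selection(
    grids: dict[str, Grid],
    features: list[LinearFeature],
    fixes: pd.DataFrame,
    cleaning_cfg: CleaningConfig | None = None,
    path_cfg: PathConfig | None = None,
    spec: ModelSpec | None = None,
    n_random: int = 10,
    seed: int = 0,
    spacing: float | None = None,
    home_ranges: dict | None = None,
    random_slopes: list[str] | None = None,
) -> PipelineResult:
    """Full path-selection analysis over in-memory inputs.

    ``grids`` must contain ``dem`` plus the covariate layers; disturbance
    layers are the log-flattened distance rasters.  Encounter polygons come
    from ``home_ranges`` (animal -> shapely polygon) or, failing that, from
    the plain-KDE isopleth fallback.  Terms whose covariate ends up missing
    for every path (no animal encountered the feature) are dropped from the
    model with a note.
    """
    cleaning_cfg = cleaning_cfg or CleaningConfig()
    path_cfg = path_cfg or PathConfig()
    kept, report = clean_telemetry(fixes, grids["dem"], cleaning_cfg)
    paths = segment_paths(kept, path_cfg)
    eligible = eligible_animals(paths, path_cfg)
    paths = [p for p in paths if p.animal_id in eligible]
    if not paths:
        raise ValueError("no qualifying paths from eligible animals; nothing to fit")
    dists = step_stats(paths)
    rng = np.random.default_rng(seed)
    extent = grids["dem"]
    path_sets = [
        generate_random_paths(p, dists, n_random=n_random, rng=rng, extent=extent)
        for p in paths
        if p.n_steps >= 2
    ]
    cov_grids = {n: grids[n] for n in COVARIATE_NAMES if n in grids}
    design = build_design(path_sets, cov_grids, spacing)
    enc = None
    if any(t in cov_grids for t in FEATURE_TYPES):
        hr = home_ranges if home_ranges is not None else _home_range_polygons(kept, seed + 1)
        if hr:
            enc = encounters(hr, features)
            design = gate_features(design, enc)
    present = [c for c in cov_grids if not design[c].isna().all()]
    design_z, transform = standardize(design, present)
    if spec is None:
        terms = []
        for t in ["slope", "slope^2", "wash", "wash^2", "veg", "veg^2", "habitat",
                  "road", "fence", "floodcontrol", "rail"]:
            base = t[:-2] if t.endswith("^2") else t
            if base in present:
                terms.append(t)
        spec = ModelSpec(terms)
    else:
        dropped = [t for t in spec.terms if any(p not in present for p in _parents(t))]
        if dropped:
            spec = ModelSpec(
                [t for t in spec.terms if t not in dropped],
                label=spec.label + f" (dropped uninformed: {', '.join(dropped)})",
            )
    strata = StratumData.from_design(design_z, spec)
    if random_slopes:
        rs = [t for t in random_slopes if t in spec.terms]
        fitted = fit_random_slopes(strata, rs, spec, seed=seed + 2)
    else:
        fitted = fit_fixed(strata, spec)
    counts = {
        "n_fixes_in": int(len(fixes)),
        "n_fixes_kept": int(len(kept)),
        "n_removed": int(len(report)),
        "n_paths": len(paths),
        "n_eligible_animals": len(eligible),
        "n_strata": strata.n_strata,
    }
    return PipelineResult(
        fitted=fitted, strata=strata, design=design_z, transform=transform,
        dists=dists, path_sets=path_sets, kept_fixes=kept, removal_report=report,
        encounter_table=enc, spec=spec, counts=counts,
    )


def _parents(term: str) -> list[str]:
    if ":" in term:
        return term.split(":")
    if term.endswith("^2"):
        return [term[:-2]]
    return [term]


def _sha256(path: FsPath) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    telemetry_csv,
    raster_paths: dict[str, str],
    features_geojson,
    out_dir,
    seed: int = 0,
    cleaning_cfg: CleaningConfig | None = None,
    path_cfg: PathConfig | None = None,
    n_random: int = 10,
) -> dict:
    """File-based pipeline wrapper: reads inputs, runs the analysis, writes
    per-stage artifacts and a manifest with input hashes and stage counts."""
    from .features import read_features_geojson
    from .grid import read_ascii_grid
    from .io import read_telemetry_csv, write_fitted_model_json, write_paths_csv

    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixes = read_telemetry_csv(telemetry_csv)
    grids = {name: read_ascii_grid(p) for name, p in raster_paths.items()}
    features = read_features_geojson(features_geojson)
    res = run_path_selection(
        grids, features, fixes, cleaning_cfg=cleaning_cfg, path_cfg=path_cfg,
        n_random=n_random, seed=seed,
    )
    res.removal_report.to_csv(out / "removed_fixes.csv", index=False)
    write_paths_csv(res.path_sets, out / "paths.csv")
    res.design.to_csv(out / "design.csv", index=False)
    write_fitted_model_json(res.fitted, out / "fit.json", transform=res.transform)
    manifest = {
        "seed": seed,
        "derived_seeds": {"random_paths": seed, "home_ranges": seed + 1, "random_slopes": seed + 2},
        "inputs": {
            "telemetry": _sha256(FsPath(telemetry_csv)),
            "features": _sha256(FsPath(features_geojson)),
            "rasters": {n: _sha256(FsPath(p)) for n, p in raster_paths.items()},
        },
        "counts": res.counts,
        "model": res.spec.label,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
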