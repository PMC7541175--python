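"""CSV/JSON round-trips for telemetry, paths, designs and fitted models.

Telemetry CSV dialect: comma separated, header required, UTF-8, '.' decimal,
ISO-8601 UTC timestamps.  Timestamps carrying a non-UTC offset are rejected
rather than silently converted — field loggers record UTC, and local-time
inputs are an analysis-time ambiguity.
"""

from __future__ import annotations

import json
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from .model import FittedModel
from .paths import Path
from .randomwalk import RandomPathSet

__all__ = [
    "read_telemetry_csv",
    "write_telemetry_csv",
    "write_paths_csv",
    "read_paths_csv",
    "fitted_model_to_dict",
    "write_fitted_model_json",
]


def read_telemetry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"animal_id", "timestamp", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"telemetry CSV missing columns: {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    raw = df["timestamp"].astype(str)
    offsets = raw.str.extract(r"([+-]\d{2}:?\d{2})$")[0].dropna()
    bad = offsets[~offsets.isin(["+00:00", "+0000", "-00:00", "-0000"])]
    if len(bad):
        raise ValueError(
            f"non-UTC timestamp offsets rejected (e.g. {bad.iloc[0]!r}); supply UTC"
        )
    df = df.copy()
    df["timestamp"] = ts.dt.tz_localize(None)
    if "elev" not in df.columns:
        df["elev"] = np.nan
    return df.sort_values(["animal_id", "timestamp"]).reset_index(drop=True)


def write_telemetry_csv(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def write_paths_csv(path_sets: list[RandomPathSet], path) -> None:
    """One row per fix, with stratum_id, path_id and role."""
    rows = []
    for ps in path_sets:
        for p in ps.all_paths:
            role = "observed" if p.is_observed else "random"
            for i, (x, y) in enumerate(p.coords):
                rows.append(
                    {
                        "stratum_id": ps.stratum_id, "path_id": p.path_id,
                        "animal_id": p.animal_id, "role": role,
                        "vertex": i, "x": x, "y": y,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_paths_csv(path) -> list[RandomPathSet]:
    df = pd.read_csv(path)
    sets = []
    for sid, grp in df.groupby("stratum_id", sort=False):
        obs = None
        rand = []
        for pid, pg in grp.groupby("path_id", sort=False):
            pg = pg.sort_values("vertex")
            p = Path(
                animal_id=str(pg["animal_id"].iloc[0]),
                coords=pg[["x", "y"]].to_numpy(),
                is_observed=pg["role"].iloc[0] == "observed",
                path_id=str(pid),
            )
            if p.is_observed:
                obs = p
            else:
                rand.append(p)
        if obs is None:
            raise ValueError(f"stratum {sid!r} has no observed path")
        sets.append(RandomPathSet(observed=obs, random_paths=rand, stratum_id=str(sid)))
    return sets


def fitted_model_to_dict(fm: FittedModel) -> dict:
    d = {
        "label": fm.label,
        "method": fm.method,
        "terms": fm.terms,
        "beta": fm.beta.tolist(),
        "se": fm.se.tolist(),
        "loglik": fm.loglik,
        "converged": fm.converged,
        "n_strata_used": fm.n_strata_used,
        "n_strata_total": fm.n_strata_total,
        "notes": fm.notes,
    }
    if fm.random_sd is not None:
        d["random_terms"] = fm.random_terms
        d["random_sd"] = np.asarray(fm.random_sd).tolist()
    if fm.waic_ is not None:
        d["waic"] = fm.waic_
        d["p_waic"] = fm.p_waic_
    return d


def write_fitted_model_json(fm: FittedModel, path, transform: dict | None = None) -> None:
    d = fitted_model_to_dict(fm)
    if transform is not None:
        d["standardization"] = {k: list(v) for k, v in transform.items()}
    FsPath(path).write_text(json.dumps(d, indent=2))
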