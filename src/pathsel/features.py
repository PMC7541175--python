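"""Linear anthropogenic features (roads, fences, flood-control berms, rail).

Features are typed polylines in the shared projected metric CRS. They are
read from / written to GeoJSON FeatureCollections whose features carry a
``feature_type`` property; geometry is handled with shapely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, mapping, shape

FEATURE_TYPES = ("road", "fence", "floodcontrol", "rail")

__all__ = ["FEATURE_TYPES", "LinearFeature", "read_features_geojson", "write_features_geojson"]


@dataclass
class LinearFeature:
    feature_type: str
    polyline: np.ndarray  # (n, 2) vertex coordinates, metres
    id: str = ""
    crs_tag: str = ""

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(
                f"feature_type must be one of {FEATURE_TYPES}, got {self.feature_type!r}"
            )
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 2 or len(self.polyline) < 2:
            raise ValueError("polyline needs >= 2 (x, y) vertices")
        seg = np.diff(self.polyline, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("consecutive polyline vertices must be distinct")

    @property
    def geometry(self) -> LineString:
        return LineString(self.polyline)

    @property
    def length(self) -> float:
        seg = np.diff(self.polyline, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def read_features_geojson(path: str | Path, crs_tag: str = "") -> list[LinearFeature]:
    data = json.loads(Path(path).read_text())
    feats = []
    for i, f in enumerate(data.get("features", [])):
        geom = shape(f["geometry"])
        ftype = f.get("properties", {}).get("feature_type")
        if ftype is None:
            raise ValueError(f"feature {i} lacks a feature_type property")
        fid = str(f.get("properties", {}).get("id", i))
        lines = [geom] if geom.geom_type == "LineString" else list(geom.geoms)
        for j, line in enumerate(lines):
            feats.append(
                LinearFeature(
                    feature_type=ftype,
                    polyline=np.asarray(line.coords),
                    id=fid if len(lines) == 1 else f"{fid}.{j}",
                    crs_tag=crs_tag,
                )
            )
    return feats


def write_features_geojson(features: list[LinearFeature], path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": {"feature_type": f.feature_type, "id": f.id},
            }
            for f in features
        ],
    }
    Path(path).write_text(json.dumps(fc))
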