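"""Vector I/O and geodesic helpers.

Polygons and points travel as GeoJSON FeatureCollections (plain ``json``
plus :mod:`shapely`); areas in km² are computed on a cylindrical
equal-area projection; distances are great-circle (haversine).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform

__all__ = [
    "EARTH_RADIUS_KM",
    "KM_PER_DEG_LAT",
    "read_geojson",
    "write_geojson",
    "equal_area_km2",
    "haversine_km",
    "point_to_geom_km",
]

#: Authalic Earth radius (km) — radius of the sphere with Earth's surface area.
EARTH_RADIUS_KM = 6371.0088

#: Meridional kilometres per degree of latitude on the authalic sphere.
KM_PER_DEG_LAT = EARTH_RADIUS_KM * math.pi / 180.0


def read_geojson(path: str | Path) -> list[dict]:
    """Read a GeoJSON FeatureCollection into ``[{geometry, **properties}]``.

    Each returned dict holds the shapely geometry under ``"geometry"`` and
    the feature's properties flattened alongside it.
    """
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    out = []
    for feat in data["features"]:
        rec = dict(feat.get("properties") or {})
        rec["geometry"] = shape(feat["geometry"])
        out.append(rec)
    return out


def write_geojson(records: Iterable[dict], path: str | Path) -> None:
    """Write ``[{geometry, **properties}]`` dicts as a GeoJSON FeatureCollection."""
    feats = []
    for rec in records:
        props = {k: v for k, v in rec.items() if k != "geometry"}
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(rec["geometry"]),
            }
        )
    payload = {"type": "FeatureCollection", "features": feats}
    Path(path).write_text(json.dumps(payload, indent=None, sort_keys=True))


def _lambert_cea(lon, lat):
    # Lambert cylindrical equal-area on the authalic sphere, output in km.
    x = np.deg2rad(np.asarray(lon, dtype=float)) * EARTH_RADIUS_KM
    y = np.sin(np.deg2rad(np.asarray(lat, dtype=float))) * EARTH_RADIUS_KM
    return x, y


def equal_area_km2(geom: BaseGeometry) -> float:
    """Area of a lon/lat geometry in km² under an equal-area projection."""
    return float(transform(_lambert_cea, geom).area)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km between WGS84 points (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def point_to_geom_km(lon: float, lat: float, geom: BaseGeometry) -> float:
    """Minimum great-circle distance (km) from a point to a geometry.

    Zero when the geometry covers the point.  Otherwise the nearest point
    is located in lon/lat space (a small-angle approximation) and the
    distance to it is measured along the great circle.
    """
    pt = shapely.points(lon, lat)
    if geom.covers(pt):
        return 0.0
    near = shapely.ops.nearest_points(geom, pt)[0]
    return float(haversine_km(lon, lat, near.x, near.y))
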