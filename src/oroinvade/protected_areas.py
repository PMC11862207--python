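"""Protected-area filtering, record overlap and category summaries.

Status filtering follows the designated/inscribed/established rule with
an assigned IUCN category; PA-in-mountain areas are measured on an
equal-area projection; a record inside several overlapping PAs counts in
each containing PA's category, while species richness is de-duplicated
within a category.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .geoio import equal_area_km2

__all__ = ["filter_pas", "pa_overlap", "pa_summaries", "IUCN_CATEGORIES"]

IUCN_CATEGORIES = ("Ia", "Ib", "II", "III", "IV", "V", "VI")

_VALID_STATUS = {"designated", "inscribed", "established"}

#: WDPA dialect values that mean "no category assigned".
_UNASSIGNED = {None, "", "not reported", "not assigned", "not applicable", "unassigned"}


def filter_pas(pas) -> tuple[list, pd.DataFrame]:
    """Keep PAs with an accepted status and an assigned IUCN category.

    Returns ``(kept, rejected_log)`` where the log lists each rejected
    PA with the reason.
    """
    kept, log = [], []
    for pa in pas:
        status_ok = (pa.status or "").strip().lower() in _VALID_STATUS
        cat = pa.iucn_category
        cat_norm = None if cat is None or str(cat).strip().lower() in _UNASSIGNED else str(cat).strip()
        if cat_norm is not None and cat_norm not in IUCN_CATEGORIES:
            log.append({"pa_id": pa.pa_id, "reason": f"unknown category {cat!r}"})
            continue
        if not status_ok:
            log.append({"pa_id": pa.pa_id, "reason": f"status {pa.status!r}"})
            continue
        if cat_norm is None:
            log.append({"pa_id": pa.pa_id, "reason": "no IUCN category"})
            continue
        pa.iucn_category = cat_norm
        kept.append(pa)
    return kept, pd.DataFrame(log, columns=["pa_id", "reason"])


def pa_overlap(kept_records: pd.DataFrame, pas) -> pd.DataFrame:
    """Annotate alien records with every containing PA.

    Returns a long table with one row per (record, containing PA);
    records outside all PAs are absent from it.
    """
    if len(kept_records) == 0 or not pas:
        return pd.DataFrame(columns=[*kept_records.columns, "pa_id", "iucn_category"])
    lons = kept_records["lon"].to_numpy(float)
    lats = kept_records["lat"].to_numpy(float)
    pts = shapely.points(lons, lats)
    tree = STRtree(pts)
    frames = []
    for pa in pas:
        idx = tree.query(pa.polygon, predicate="intersects")
        if idx.size == 0:
            continue
        inside = shapely.contains_xy(pa.polygon, lons[idx], lats[idx]) | shapely.intersects_xy(
            shapely.boundary(pa.polygon), lons[idx], lats[idx]
        )
        hit = np.sort(idx[inside])
        if hit.size == 0:
            continue
        sub = kept_records.iloc[hit].copy()
        sub["pa_id"] = pa.pa_id
        sub["iucn_category"] = pa.iucn_category
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=[*kept_records.columns, "pa_id", "iucn_category"])
    return pd.concat(frames, ignore_index=True)


def mountain_portion_areas(pas, mountains) -> dict:
    """km² of each PA inside the union of mountain polygons (equal-area)."""
    union = shapely.unary_union([m.polygon for m in mountains])
    out = {}
    for pa in pas:
        inter = pa.polygon.intersection(union)
        area = 0.0 if inter.is_empty else equal_area_km2(inter)
        pa.area_in_mountains = area
        out[pa.pa_id] = area
    return out


def pa_summaries(
    annotated: pd.DataFrame, pas, mountains, realms=None
) -> dict:
    """Per-category and per-realm×category summaries of PA incidence.

    Returns a dict with:

    - ``per_category``: records and distinct species per IUCN category
      (overall and per taxon class), plus densities per km² of the
      category's mountain-portion area (NaN when that area is zero);
    - ``per_realm_category``: cumulative species richness per realm ×
      category (requires ``realm_id`` on the annotated records);
    - ``species_only_in_pas`` is left to the caller (needs the full kept
      set) — see :func:`species_exclusive_to_pas`.
    """
    areas = mountain_portion_areas(pas, mountains)
    cat_area = {}
    for pa in pas:
        cat_area[pa.iucn_category] = cat_area.get(pa.iucn_category, 0.0) + areas[pa.pa_id]

    rows = []
    for cat in IUCN_CATEGORIES:
        sub = annotated[annotated["iucn_category"] == cat]
        area = cat_area.get(cat, 0.0)
        row = {
            "iucn_category": cat,
            "n_records": len(sub),
            "n_species": sub["species_id"].nunique(),
            "area_in_mountains_km2": area,
        }
        for cls in sorted(annotated["taxon_class"].unique()) if len(annotated) else []:
            cs = sub[sub["taxon_class"] == cls]
            row[f"n_records_{cls}"] = len(cs)
            row[f"n_species_{cls}"] = cs["species_id"].nunique()
        if area > 0:
            row["records_per_km2"] = row["n_records"] / area
            row["species_per_km2"] = row["n_species"] / area
        else:
            row["records_per_km2"] = float("nan")
            row["species_per_km2"] = float("nan")
        rows.append(row)
    per_category = pd.DataFrame(rows)

    per_realm = None
    if realms is not None and "realm_id" in annotated.columns:
        per_realm = (
            annotated.groupby(["realm_id", "iucn_category"])["species_id"]
            .nunique()
            .rename("n_species")
            .reset_index()
        )
    return {"per_category": per_category, "per_realm_category": per_realm}


def species_exclusive_to_pas(kept_records: pd.DataFrame, annotated: pd.DataFrame) -> set:
    """Species whose every kept record lies inside at least one PA."""
    all_species = set(kept_records["species_id"])
    in_pa_records = set(annotated["record_id"]) if len(annotated) else set()
    exclusive = set()
    for species_id, grp in kept_records.groupby("species_id"):
        if set(grp["record_id"]) <= in_pa_records:
            exclusive.add(species_id)
    return exclusive & all_species
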