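"""Occurrence ingestion: mountain assignment, native-range alien filter,
richness/record-density tables and completeness residuals.

Containment is tested in lon/lat with boundary points counted as inside;
records on a shared mountain border resolve to the lexicographically
smallest ``mountain_id``.  Areas always come from the mountain attribute
table, never from re-measured polygons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

__all__ = [
    "validate_disjoint",
    "assign_mountain",
    "filter_native_overlap",
    "richness_table",
    "completeness_residuals",
]


def _covers_points(geom, lons, lats):
    """Vectorized covers: interior or boundary contact."""
    return shapely.contains_xy(geom, lons, lats) | shapely.intersects_xy(
        shapely.boundary(geom), lons, lats
    )


def validate_disjoint(mountains) -> None:
    """Raise listing offending pairs if any two mountain polygons overlap."""
    polys = [m.polygon for m in mountains]
    tree = STRtree(polys)
    offenders = []
    for i, poly in enumerate(polys):
        for j in tree.query(poly, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            if poly.intersection(polys[j]).area > 1e-12:
                offenders.append((mountains[i].mountain_id, mountains[j].mountain_id))
    if offenders:
        raise ValueError(f"overlapping mountain polygons: {offenders}")


def assign_mountain(records: pd.DataFrame, mountains) -> pd.DataFrame:
    """Annotate records with the id of the mountain containing them.

    Records outside every polygon get ``mountain_id = NaN``; points on a
    shared boundary go to the lexicographically smallest id.  Mountains
    must be pairwise disjoint (validated).
    """
    validate_disjoint(mountains)
    out = records.copy()
    out["mountain_id"] = pd.array([None] * len(out), dtype="object")
    if len(out) == 0 or not mountains:
        return out
    pts = shapely.points(out["lon"].to_numpy(float), out["lat"].to_numpy(float))
    tree = STRtree(pts)
    assigned = {}
    for m in sorted(mountains, key=lambda m: m.mountain_id):
        idx = tree.query(m.polygon, predicate="intersects")
        if idx.size == 0:
            continue
        lons = out["lon"].to_numpy(float)[idx]
        lats = out["lat"].to_numpy(float)[idx]
        hit = idx[_covers_points(m.polygon, lons, lats)]
        for i in hit:
            assigned.setdefault(int(i), m.mountain_id)  # first == smallest id wins
    col = out.columns.get_loc("mountain_id")
    for i, mid in assigned.items():
        out.iat[i, col] = mid
    return out


def filter_native_overlap(
    records: pd.DataFrame, ranges
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (kept == alien, discarded == within native range).

    A record is discarded iff its point falls inside (or on the boundary
    of) a native polygon *of its own species*.  Species absent from the
    range set are kept and flagged ``range_unknown`` rather than dropped.
    Returns ``(kept, discarded)``; kept rows carry ``alien=True``.
    """
    by_species = {r.species_id: r for r in ranges}
    lons = records["lon"].to_numpy(float)
    lats = records["lat"].to_numpy(float)
    discard = np.zeros(len(records), dtype=bool)
    unknown = np.zeros(len(records), dtype=bool)
    n_unknown_species = set()
    for species_id, idx in records.groupby("species_id").indices.items():
        rng = by_species.get(species_id)
        if rng is None or rng.native_polygons is None or rng.native_polygons.is_empty:
            unknown[idx] = True
            n_unknown_species.add(species_id)
            continue
        discard[idx] = _covers_points(rng.native_polygons, lons[idx], lats[idx])
    if n_unknown_species:
        warnings.warn(
            f"{len(n_unknown_species)} species without native-range polygons; "
            f"their {int(unknown.sum())} records are kept and flagged range_unknown",
            stacklevel=2,
        )
    kept = records.loc[~discard].copy()
    kept["alien"] = True
    kept["range_unknown"] = unknown[~discard]
    discarded = records.loc[discard].copy()
    discarded["alien"] = False
    return kept, discarded


def richness_table(kept: pd.DataFrame, mountains) -> pd.DataFrame:
    """Per-mountain species counts, record counts and record density.

    One row per (mountain, taxon_class) plus an ``all`` row per mountain;
    density is records / mountain area (km²) from the attribute table.
    Mountains with no kept assigned records are omitted; unassigned
    records are ignored.
    """
    area = {m.mountain_id: m.area_km2 for m in mountains}
    if "mountain_id" not in kept.columns:
        kept = kept.assign(mountain_id=pd.array([None] * len(kept), dtype="object"))
    df = kept.dropna(subset=["mountain_id"])
    rows = []
    for (mid, cls), grp in df.groupby(["mountain_id", "taxon_class"]):
        rows.append(
            {
                "mountain_id": mid,
                "taxon_class": cls,
                "n_species": grp["species_id"].nunique(),
                "n_records": len(grp),
            }
        )
    for mid, grp in df.groupby("mountain_id"):
        rows.append(
            {
                "mountain_id": mid,
                "taxon_class": "all",
                "n_species": grp["species_id"].nunique(),
                "n_records": len(grp),
            }
        )
    out = pd.DataFrame(rows, columns=["mountain_id", "taxon_class", "n_species", "n_records"])
    if len(out):
        out["record_density"] = out["n_records"] / out["mountain_id"].map(area)
        out = out.sort_values(["mountain_id", "taxon_class"]).reset_index(drop=True)
    else:
        out["record_density"] = pd.Series(dtype=float)
    return out


def completeness_residuals(
    richness: pd.Series, completeness: pd.Series
) -> pd.Series:
    """OLS residuals of richness on sampling completeness, by mountain.

    Positive residual == richness above the sampling-effort expectation.
    Constant completeness degenerates to an intercept-only model (with a
    warning): residual = deviation from the mean.
    """
    joined = pd.concat(
        [richness.rename("rich"), completeness.rename("comp")], axis=1, join="inner"
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 mountains with richness and completeness")
    y = joined["rich"].to_numpy(float)
    x = joined["comp"].to_numpy(float)
    if np.ptp(x) == 0.0:
        warnings.warn("constant completeness; falling back to intercept-only model", stacklevel=2)
        resid = y - y.mean()
    else:
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
    return pd.Series(resid, index=joined.index, name="completeness_residual")
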