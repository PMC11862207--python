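"""Donor→recipient realm flow matrices and the resampling null test.

A species native to realms D with alien records in recipient realms R
adds one to every (d, r) cell, diagonal included.  The null resamples,
for each recipient realm, as many species as were observed there from
the global native pool (without replacement) and tallies their
native-realm composition; verdicts use the empirical 2.5% / 97.5% order
statistics of the draws with strict inequality, which is the
conservative reading for discrete counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

__all__ = ["FlowMatrix", "assign_realms", "flow_matrix", "null_flow_test", "export_chord"]


@dataclass
class FlowMatrix:
    realms: list
    counts: pd.DataFrame  # donor (rows) x recipient (cols)
    taxon_scope: str = "all"
    #: distinct observed alien species per recipient realm (the k_r of the null)
    species_per_recipient: dict | None = None


def _point_realm(realms, lons, lats):
    """Realm id containing each point (lexicographic tie-break); None if outside all."""
    out = np.array([None] * len(lons), dtype=object)
    for r in sorted(realms, key=lambda r: r["realm_id"]):
        geom = r["geometry"]
        hit = shapely.contains_xy(geom, lons, lats) | shapely.intersects_xy(
            shapely.boundary(geom), lons, lats
        )
        fill = hit & (out == None)  # noqa: E711  (elementwise)
        out[fill] = r["realm_id"]
    return out


def assign_realms(ranges, realms, records: pd.DataFrame) -> pd.DataFrame:
    """Derive native realms for each range and a recipient realm per record.

    Native realms are those whose polygons share positive area with the
    species' native polygons (mere boundary contact does not count, since
    realms tile space and share borders).  Records outside every realm
    are excluded with a warning.  Mutates ``ranges`` in place and returns
    the annotated record table.
    """
    for rng in ranges:
        if rng.native_polygons is None or rng.native_polygons.is_empty:
            rng.native_realms = set()
            continue
        rng.native_realms = {
            r["realm_id"]
            for r in realms
            if r["geometry"].intersection(rng.native_polygons).area > 1e-12
        }
    out = records.copy()
    realm_ids = _point_realm(
        realms, out["lon"].to_numpy(float), out["lat"].to_numpy(float)
    )
    out["realm_id"] = realm_ids
    n_out = int(pd.isna(out["realm_id"]).sum())
    if n_out:
        warnings.warn(f"{n_out} records outside all realms were excluded", stacklevel=2)
        out = out[~pd.isna(out["realm_id"])].copy()
    return out


def flow_matrix(kept: pd.DataFrame, ranges, taxon_scope: str = "all") -> FlowMatrix:
    """Count species flows donor realm → recipient realm.

    ``kept`` must be alien-filtered and realm-annotated.  A species with
    native realms D and alien records in realms R contributes one to each
    (d, r) pair; intra-realm (diagonal) flows are legitimate.
    """
    realm_ids = sorted({r for rng in ranges for r in rng.native_realms} | set(kept["realm_id"].dropna()))
    counts = pd.DataFrame(0, index=realm_ids, columns=realm_ids, dtype=int)
    df = kept if taxon_scope == "all" else kept[kept["taxon_class"] == taxon_scope]
    donors = {rng.species_id: rng.native_realms for rng in ranges}
    species_per_recipient: dict[str, int] = {r: 0 for r in realm_ids}
    for species_id, grp in df.groupby("species_id"):
        d_set = donors.get(species_id, set())
        r_set = set(grp["realm_id"].dropna())
        for r in r_set:
            species_per_recipient[r] = species_per_recipient.get(r, 0) + 1
        for d in d_set:
            for r in r_set:
                counts.loc[d, r] += 1
    return FlowMatrix(
        realms=realm_ids,
        counts=counts,
        taxon_scope=taxon_scope,
        species_per_recipient=species_per_recipient,
    )


def _pool_categories(pool: pd.DataFrame, realm_ids):
    """Group pool species by their (frozen) native realm set.

    Returns (category sizes, donor incidence matrix category x realm).
    """
    key = pool["native_realms"].map(lambda s: tuple(sorted(s)))
    sizes = key.value_counts().sort_index()
    cats = list(sizes.index)
    incidence = np.zeros((len(cats), len(realm_ids)), dtype=np.int64)
    pos = {r: j for j, r in enumerate(realm_ids)}
    for i, cat in enumerate(cats):
        for r in cat:
            if r in pos:
                incidence[i, pos[r]] = 1
    return sizes.to_numpy(), incidence


def null_flow_test(
    observed: FlowMatrix,
    pool: pd.DataFrame,
    n_draws: int = 999,
    seed: int = 42,
) -> pd.DataFrame:
    """Test each flow cell against a resampling null from the global pool.

    ``pool`` has one row per species with a ``native_realms`` set (every
    member must carry at least one realm).  For each recipient realm the
    observed number of alien species is redrawn ``n_draws`` times without
    replacement from the pool; each sampled species adds one simulated
    count to every one of its native realms.  Returns a long table with
    observed, null quantiles and a verdict per (donor, recipient) cell.
    """
    if (pool["native_realms"].map(len) == 0).any():
        raise ValueError("every pool species must have at least one native realm")
    realm_ids = list(observed.counts.index)
    rng = np.random.default_rng(seed)
    sizes, incidence = _pool_categories(pool, realm_ids)
    pool_n = int(sizes.sum())

    # k_r is the number of distinct observed alien species per recipient
    # realm; the matrix columns over-count multi-realm natives, so it is
    # carried as metadata by flow_matrix().
    k_by_recipient = observed.species_per_recipient
    if k_by_recipient is None:
        raise ValueError(
            "FlowMatrix lacks species_per_recipient metadata; build it with flow_matrix()"
        )

    out_rows = []
    for recipient in realm_ids:
        k_r = int(k_by_recipient.get(recipient, 0))
        if k_r > pool_n:
            raise ValueError(
                f"recipient {recipient}: observed species count {k_r} exceeds pool size {pool_n}"
            )
        null = np.zeros((n_draws, len(realm_ids)), dtype=np.int64)
        if k_r > 0:
            for b in range(n_draws):
                take = rng.multivariate_hypergeometric(sizes, k_r)
                null[b] = take @ incidence
        null_sorted = np.sort(null, axis=0)
        q025 = null_sorted[max(0, int(np.ceil(0.025 * n_draws)) - 1)]
        q50 = null_sorted[int(np.ceil(0.5 * n_draws)) - 1]
        q975 = null_sorted[int(np.ceil(0.975 * n_draws)) - 1]
        for j, donor in enumerate(realm_ids):
            obs = int(observed.counts.loc[donor, recipient])
            if obs > q975[j]:
                verdict = "higher"
            elif obs < q025[j]:
                verdict = "lower"
            else:
                verdict = "ns"
            out_rows.append(
                {
                    "donor": donor,
                    "recipient": recipient,
                    "observed": obs,
                    "q025": int(q025[j]),
                    "q50": int(q50[j]),
                    "q975": int(q975[j]),
                    "verdict": verdict,
                    "n_draws": n_draws,
                    "seed": seed,
                }
            )
    return pd.DataFrame(out_rows)


def export_chord(matrix: FlowMatrix) -> pd.DataFrame:
    """Long-format (donor, recipient, count) rows; zero cells omitted."""
    rows = [
        {"donor": d, "recipient": r, "count": int(matrix.counts.loc[d, r])}
        for d in matrix.counts.index
        for r in matrix.counts.columns
        if matrix.counts.loc[d, r] > 0
    ]
    return pd.DataFrame(rows, columns=["donor", "recipient", "count"])
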