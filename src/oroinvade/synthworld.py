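"""Synthetic world generator with known ground truth.

Builds a self-contained landscape — realms tiling a lon/lat extent,
disjoint mountain polygons with a system ⊂ region ⊂ continent hierarchy,
a DEM whose per-mountain elevation distributions force intended geometry
classes, predictor rasters, a monthly climate stack, species with
polygonal native ranges, occurrence records that are a known mixture of
native and alien points, and protected areas — so every downstream stage
of the pipeline can be tested offline against exact truth.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import box

from ._seeds import substream
from .geoio import equal_area_km2, write_geojson
from .raster import Raster, zonal_mask

__all__ = [
    "TAXON_CLASSES",
    "WorldConfig",
    "GroundTruth",
    "SyntheticWorld",
    "Mountain",
    "SpeciesRange",
    "ProtectedArea",
    "generate_world",
    "simulate_occurrences",
    "simulate_richness_counts",
    "simulate_climate_series",
    "random_design",
    "write_world",
]

TAXON_CLASSES = ("fish", "amphibian", "reptile", "bird", "mammal")

GEOMETRY_CLASSES = ("pyramid", "inverse_pyramid", "diamond", "hourglass")

#: Beta-distribution shapes (and bimodal mixtures) whose skew/modality
#: force the intended geometry class of a mountain's elevation sample.
_GEOMETRY_RECIPES = {
    "pyramid": ("beta", 1.2, 4.0),
    "inverse_pyramid": ("beta", 4.0, 1.2),
    "diamond": ("beta", 5.0, 5.0),
    "hourglass": ("bimodal", (0.15, 0.05), (0.85, 0.05)),
}


@dataclass
class Mountain:
    mountain_id: str
    polygon: shapely.Geometry
    system_id: str
    region_id: str
    continent_id: str
    area_km2: float
    elev_min: float = float("nan")
    elev_max: float = float("nan")


@dataclass
class SpeciesRange:
    species_id: str
    taxon_class: str
    native_polygons: shapely.Geometry | None  # None or empty == range unknown
    native_realms: set = field(default_factory=set)


@dataclass
class ProtectedArea:
    pa_id: str
    polygon: shapely.Geometry
    status: str
    iucn_category: str | None  # None == unassigned
    area_in_mountains: float | None = None


@dataclass
class WorldConfig:
    """Scale knobs for the synthetic world."""

    n_realms: int = 6
    n_mountains: int = 40
    n_species_pool: int = 150
    taxon_class_weights: dict = field(
        default_factory=lambda: {
            "fish": 0.14,
            "amphibian": 0.08,
            "reptile": 0.11,
            "bird": 0.44,
            "mammal": 0.23,
        }
    )
    grid_extent: tuple = (0.0, 0.0, 40.0, 40.0)  # lon_min, lat_min, lon_max, lat_max
    raster_resolution: float = 0.25
    seed: int = 0
    # plumbing knobs beyond the core contract
    n_cities: int = 25
    n_ports: int = 12
    n_pas: int = 40
    climate_years: int = 30
    alien_fraction: float = 0.5
    records_per_species: float = 20.0

    def validate(self) -> None:
        for name in ("n_realms", "n_mountains", "n_species_pool"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        w = sum(self.taxon_class_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"taxon_class_weights must sum to 1 (got {w})")
        if set(self.taxon_class_weights) - set(TAXON_CLASSES):
            raise ValueError("unknown taxon class in weights")
        x0, y0, x1, y1 = self.grid_extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError("degenerate grid_extent")
        if self.raster_resolution <= 0:
            raise ValueError("raster_resolution must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    alien_flags: pd.Series | None = None  # by record_id: True == truth-alien
    record_mountain: pd.Series | None = None  # mountain each alien record was placed in
    richness: pd.DataFrame | None = None  # mountain_id x taxon_class true alien richness
    flow: pd.DataFrame | None = None  # donor x recipient true species counts
    geometry_class: dict = field(default_factory=dict)  # mountain_id -> intended class
    beta: dict = field(default_factory=dict)
    theta: float | None = None
    sigma: dict = field(default_factory=dict)
    random_effects: dict = field(default_factory=dict)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    realms: list  # [{realm_id, geometry}]
    mountains: list  # [Mountain]
    dem: Raster
    predictor_rasters: dict  # name -> Raster
    climate_series: "object"  # xarray.DataArray (time, y, x)
    cities: pd.DataFrame
    ports: pd.DataFrame
    species: list  # [SpeciesRange]
    occurrences: pd.DataFrame | None
    pas: list  # [ProtectedArea]
    truth: GroundTruth


# --------------------------------------------------------------------------- realms


def _slice_dice(extent, n, rng):
    """Tile a rectangle into ``n`` rectangles by recursive random splits."""
    x0, y0, x1, y1 = extent
    rects = [box(x0, y0, x1, y1)]
    while len(rects) < n:
        # split the largest rectangle across its longer side
        areas = [r.area for r in rects]
        i = int(np.argmax(areas))
        minx, miny, maxx, maxy = rects[i].bounds
        f = 0.35 + 0.3 * rng.random()
        if (maxx - minx) >= (maxy - miny):
            xm = minx + f * (maxx - minx)
            a, b = box(minx, miny, xm, maxy), box(xm, miny, maxx, maxy)
        else:
            ym = miny + f * (maxy - miny)
            a, b = box(minx, miny, maxx, ym), box(minx, ym, maxx, maxy)
        rects[i : i + 1] = [a, b]
    return rects


def _make_realms(config: WorldConfig, rng) -> list[dict]:
    rects = _slice_dice(config.grid_extent, config.n_realms, rng)
    return [{"realm_id": f"R{i + 1:02d}", "geometry": r} for i, r in enumerate(rects)]


# ------------------------------------------------------------------------ mountains


def _make_mountains(config: WorldConfig, rng) -> list[Mountain]:
    x0, y0, x1, y1 = config.grid_extent
    n = config.n_mountains
    ncol = int(math.ceil(math.sqrt(n * (x1 - x0) / (y1 - y0))))
    nrow = int(math.ceil(n / ncol))
    cw, ch = (x1 - x0) / ncol, (y1 - y0) / nrow
    cells = [(i, j) for i in range(nrow) for j in range(ncol)]
    order = rng.permutation(len(cells))[:n]

    mountains = []
    for k, idx in enumerate(sorted(order)):
        i, j = cells[idx]
        cx0, cy0 = x0 + j * cw, y0 + i * ch
        # random convex polygon inside the central 80% of the cell
        px = cx0 + cw * (0.1 + 0.8 * rng.random(10))
        py = cy0 + ch * (0.1 + 0.8 * rng.random(10))
        hull = shapely.convex_hull(shapely.multipoints(np.column_stack([px, py])))
        mountains.append(
            Mountain(
                mountain_id=f"M{k + 1:04d}",
                polygon=hull,
                system_id="",
                region_id="",
                continent_id="",
                area_km2=equal_area_km2(hull),
            )
        )

    # nested hierarchy by spatial chunks (mountains are in row-major cell order)
    n_sys = max(1, n // 4)
    n_reg = max(1, n_sys // 3)
    n_con = max(1, min(6, n_reg // 2) or 1)
    for k, m in enumerate(mountains):
        s = k * n_sys // n
        r = s * n_reg // n_sys
        c = r * n_con // n_reg
        m.system_id = f"SY{s + 1:03d}"
        m.region_id = f"RG{r + 1:03d}"
        m.continent_id = f"CT{c + 1:02d}"
    return mountains


# ---------------------------------------------------------------------------- DEM


def _make_dem(config: WorldConfig, mountains, truth: GroundTruth, rng) -> Raster:
    x0, y0, x1, y1 = config.grid_extent
    res = config.raster_resolution
    ncol = int(round((x1 - x0) / res))
    nrow = int(round((y1 - y0) / res))
    base = 50.0 + 50.0 * rng.random((nrow, ncol))  # positive lowlands
    dem = Raster(base, x0, y1, res)

    for k, m in enumerate(mountains):
        cls = GEOMETRY_CLASSES[k % len(GEOMETRY_CLASSES)]
        truth.geometry_class[m.mountain_id] = cls
        mask = zonal_mask(dem, m.polygon)
        ncell = int(mask.sum())
        if ncell == 0:
            continue
        recipe = _GEOMETRY_RECIPES[cls]
        if recipe[0] == "beta":
            v = rng.beta(recipe[1], recipe[2], ncell)
        else:
            (m1, s1), (m2, s2) = recipe[1], recipe[2]
            half = ncell // 2
            v = np.concatenate(
                [rng.normal(m1, s1, half), rng.normal(m2, s2, ncell - half)]
            )
            rng.shuffle(v)
            v = np.clip(v, 0.0, 1.0)
        dem.data[mask] = 500.0 + 2500.0 * v
        m.elev_min = float(dem.data[mask].min())
        m.elev_max = float(dem.data[mask].max())
    return dem


def _smooth_field(shape, rng, sigma=4.0):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _make_predictor_rasters(config: WorldConfig, dem: Raster, rng) -> dict:
    shape = dem.shape
    mk = lambda data: Raster(data, dem.x0, dem.y0, dem.res)
    pop = np.exp(3.0 + 1.5 * _smooth_field(shape, rng))  # persons / km2
    road = np.exp(4.0 + 1.0 * _smooth_field(shape, rng))  # m of road / km
    bii = 1.0 / (1.0 + np.exp(-1.2 * _smooth_field(shape, rng)))  # 0..1
    completeness = 1.0 / (1.0 + np.exp(-1.0 * _smooth_field(shape, rng)))  # 0..1
    return {
        "pop_density": mk(pop),
        "road_density": mk(road),
        "bii": mk(bii),
        "completeness": mk(completeness),
    }


# -------------------------------------------------------------------------- climate


def simulate_climate_series(
    template: Raster,
    trend: float = 0.02,
    spatial_gradient: float = 0.01,
    noise_sd: float = 0.0,
    years: int = 30,
    seed: int = 0,
    base: float = 5.0,
):
    """Monthly minimum-temperature stack: ``base + gradient*dist + trend*t + noise``.

    ``dist`` is the meridional distance (km) of the cell center from the
    southern edge of the grid; ``t`` is time in years from the series
    start.  Returns an ``xarray.DataArray`` with dims (time, y, x).
    """
    import xarray as xr

    from .geoio import KM_PER_DEG_LAT

    if years < 2:
        raise ValueError("years must be >= 2")
    rng = substream(seed, "climate")
    nrow, ncol = template.shape
    lat = template.y0 - (np.arange(nrow) + 0.5) * template.res
    lon = template.x0 + (np.arange(ncol) + 0.5) * template.res
    south = template.y0 - nrow * template.res
    dist_km = (lat - south) * KM_PER_DEG_LAT  # per row
    months = years * 12
    t_years = (np.arange(months) + 0.5) / 12.0
    field2d = base + spatial_gradient * dist_km[:, None] + np.zeros((nrow, ncol))
    data = field2d[None, :, :] + trend * t_years[:, None, None]
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)
    time = pd.date_range("2000-01-01", periods=months, freq="MS")
    return xr.DataArray(
        data,
        coords={"time": time, "y": lat, "x": lon},
        dims=("time", "y", "x"),
        name="tmin",
        attrs={"units": "degC", "trend_per_year": trend, "gradient_per_km": spatial_gradient},
    )


# -------------------------------------------------------------------------- species


def _sample_point_in(geom, rng, max_tries=10000):
    minx, miny, maxx, maxy = geom.bounds
    for _ in range(max_tries):
        x = minx + (maxx - minx) * rng.random()
        y = miny + (maxy - miny) * rng.random()
        if shapely.contains_xy(geom, x, y):
            return x, y
    raise RuntimeError("rejection sampling failed (degenerate geometry?)")


def _make_species(config: WorldConfig, realms, rng) -> list[SpeciesRange]:
    classes = list(config.taxon_class_weights)
    weights = np.array([config.taxon_class_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()
    # realm adjacency for occasional two-realm natives
    geoms = [r["geometry"] for r in realms]
    adjacency = {
        i: [j for j in range(len(geoms)) if j != i and geoms[i].touches(geoms[j])]
        for i in range(len(geoms))
    }
    species = []
    for s in range(config.n_species_pool):
        cls = classes[int(rng.choice(len(classes), p=weights))]
        i = int(rng.integers(len(realms)))
        chosen = [i]
        if adjacency[i] and rng.random() < 0.30:
            chosen.append(int(rng.choice(adjacency[i])))
        target = shapely.unary_union([geoms[j] for j in chosen])
        poly = None
        for _ in range(20):
            pts = [_sample_point_in(geoms[i], rng) for _ in range(6)]
            hull = shapely.convex_hull(shapely.multipoints(np.array(pts)))
            cand = hull.buffer(1.5).intersection(target)
            if not cand.is_empty and cand.area > 1e-6:
                poly = cand
                break
        if poly is None:  # extremely unlikely; give the whole realm
            poly = geoms[i]
        species.append(
            SpeciesRange(
                species_id=f"SP{s + 1:05d}",
                taxon_class=cls,
                native_polygons=poly,
            )
        )
    return species


# ------------------------------------------------------------------- protected areas

_PA_STATUSES = ("Designated", "Inscribed", "Established", "Proposed", "Adopted")
_PA_CATEGORIES = ("Ia", "Ib", "II", "III", "IV", "V", "VI", None)


def _make_pas(config: WorldConfig, mountains, rng) -> list[ProtectedArea]:
    x0, y0, x1, y1 = config.grid_extent
    pas = []
    for k in range(config.n_pas):
        # bias PA centers toward mountains so overlaps actually occur
        if mountains and rng.random() < 0.7:
            m = mountains[int(rng.integers(len(mountains)))]
            cx, cy = m.polygon.centroid.x, m.polygon.centroid.y
            cx += rng.normal(0, 0.5)
            cy += rng.normal(0, 0.5)
        else:
            cx = x0 + (x1 - x0) * rng.random()
            cy = y0 + (y1 - y0) * rng.random()
        radius = 0.2 + 0.8 * rng.random()
        poly = shapely.points(cx, cy).buffer(radius, quad_segs=8)
        status = _PA_STATUSES[int(rng.choice(len(_PA_STATUSES), p=[0.55, 0.1, 0.15, 0.15, 0.05]))]
        cat = _PA_CATEGORIES[int(rng.integers(len(_PA_CATEGORIES)))]
        pas.append(ProtectedArea(pa_id=f"PA{k + 1:04d}", polygon=poly, status=status, iucn_category=cat))
    return pas


# ------------------------------------------------------------------------ world


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a full synthetic world; deterministic for a fixed seed."""
    config.validate()
    seed = config.seed
    truth = GroundTruth()

    realms = _make_realms(config, substream(seed, "realms"))
    mountains = _make_mountains(config, substream(seed, "mountains"))
    dem = _make_dem(config, mountains, truth, substream(seed, "dem"))
    predictors = _make_predictor_rasters(config, dem, substream(seed, "predictors"))
    climate = simulate_climate_series(
        dem, trend=0.02, spatial_gradient=0.01, noise_sd=0.1, years=config.climate_years, seed=seed
    )
    rng_pts = substream(seed, "points")
    x0, y0, x1, y1 = config.grid_extent
    cities = pd.DataFrame(
        {
            "city_id": [f"CI{i + 1:03d}" for i in range(config.n_cities)],
            "lon": x0 + (x1 - x0) * rng_pts.random(config.n_cities),
            "lat": y0 + (y1 - y0) * rng_pts.random(config.n_cities),
        }
    )
    ports = pd.DataFrame(
        {
            "port_id": [f"PO{i + 1:03d}" for i in range(config.n_ports)],
            "lon": x0 + (x1 - x0) * rng_pts.random(config.n_ports),
            "lat": y0 + (y1 - y0) * rng_pts.random(config.n_ports),
        }
    )
    species = _make_species(config, realms, substream(seed, "species"))
    # derive native realms (positive-area intersection, not mere touching)
    for sp in species:
        sp.native_realms = {
            r["realm_id"]
            for r in realms
            if sp.native_polygons is not None
            and r["geometry"].intersection(sp.native_polygons).area > 1e-12
        }
    pas = _make_pas(config, mountains, substream(seed, "pas"))

    world = SyntheticWorld(
        config=config,
        realms=realms,
        mountains=mountains,
        dem=dem,
        predictor_rasters=predictors,
        climate_series=climate,
        cities=cities,
        ports=ports,
        species=species,
        occurrences=None,
        pas=pas,
        truth=truth,
    )
    world.occurrences = simulate_occurrences(
        world, config.alien_fraction, config.records_per_species, seed
    )
    return world


# --------------------------------------------------------------------- occurrences


def simulate_occurrences(
    world: SyntheticWorld,
    alien_fraction: float,
    records_per_species: float,
    seed: int,
) -> pd.DataFrame:
    """Draw occurrence records as a native/alien mixture with truth labels.

    Native points are sampled inside the species' native polygons; alien
    points inside a mountain polygon but outside the species' native
    range.  Truth flags and per-mountain/per-species tallies go to
    ``world.truth``.
    """
    if not 0.0 <= alien_fraction <= 1.0:
        raise ValueError("alien_fraction must be in [0, 1]")
    rng = substream(seed, "occurrences")
    extent_poly = box(*world.config.grid_extent)
    rows = []
    flags = []
    rec_mountain = []
    n_mnt = len(world.mountains)
    rid = 0
    skipped = []
    for sp in world.species:
        n_rec = int(rng.poisson(records_per_species))
        if n_rec == 0:
            continue
        native = sp.native_polygons
        native_covers_all = native is not None and native.covers(extent_poly)
        for _ in range(n_rec):
            is_alien = bool(rng.random() < alien_fraction)
            if is_alien and native_covers_all:
                skipped.append(sp.species_id)
                continue
            if is_alien:
                # pick mountains until one admits a point outside the native range
                placed = False
                for _try in range(50):
                    m = world.mountains[int(rng.integers(n_mnt))]
                    target = m.polygon if native is None else m.polygon.difference(native)
                    if target.is_empty or target.area <= 0:
                        continue
                    x, y = _sample_point_in(target, rng)
                    placed = True
                    break
                if not placed:
                    skipped.append(sp.species_id)
                    continue
                rec_mountain.append(m.mountain_id)
            else:
                x, y = _sample_point_in(native, rng)
                rec_mountain.append(None)
            rid += 1
            rows.append(
                {
                    "record_id": f"OC{rid:07d}",
                    "species_id": sp.species_id,
                    "taxon_class": sp.taxon_class,
                    "lon": x,
                    "lat": y,
                }
            )
            flags.append(is_alien)
    if skipped:
        warnings.warn(
            f"skipped alien draws for {len(set(skipped))} species with no room outside "
            "their native range",
            stacklevel=2,
        )
    occ = pd.DataFrame(rows, columns=["record_id", "species_id", "taxon_class", "lon", "lat"])
    truth = world.truth
    truth.alien_flags = pd.Series(flags, index=occ["record_id"], dtype=bool, name="alien")
    truth.record_mountain = pd.Series(rec_mountain, index=occ["record_id"], name="mountain_id")

    # true per-mountain richness per class, from generator-side placements
    alien_occ = occ[truth.alien_flags.to_numpy()].copy()
    alien_occ["mountain_id"] = truth.record_mountain[truth.alien_flags].to_numpy()
    rich = (
        alien_occ.groupby(["mountain_id", "taxon_class"])["species_id"].nunique().unstack(fill_value=0)
    )
    truth.richness = rich.reindex(columns=list(TAXON_CLASSES), fill_value=0)

    # true flow matrix: donors = native realms; recipients = realms of alien points
    realm_ids = [r["realm_id"] for r in world.realms]
    flow = pd.DataFrame(0, index=realm_ids, columns=realm_ids, dtype=int)
    by_species = {sp.species_id: sp for sp in world.species}
    for species_id, grp in alien_occ.groupby("species_id"):
        sp = by_species[species_id]
        recips = set()
        for _, row in grp.iterrows():
            for r in world.realms:
                if shapely.contains_xy(r["geometry"], row["lon"], row["lat"]) or shapely.intersects_xy(
                    shapely.boundary(r["geometry"]), row["lon"], row["lat"]
                ):
                    recips.add(r["realm_id"])
                    break
        for d in sp.native_realms:
            for rcp in recips:
                flow.loc[d, rcp] += 1
    truth.flow = flow
    return occ


# ------------------------------------------------------------------- count model


def simulate_richness_counts(
    design: pd.DataFrame,
    beta: dict,
    theta: float,
    sigma: dict,
    seed: int,
    intercept: float = 0.0,
) -> tuple[pd.Series, dict]:
    """Draw per-mountain NB counts from the mixed-model data-generating process.

    ``design`` needs columns ``area_km2``, ``system_id``, ``region_id``,
    ``continent_id`` and every predictor named in ``beta``.  The linear
    predictor is ``log(area) + intercept + X beta + u_continent + u_region
    + u_system`` with independent Gaussian intercepts of the SDs in
    ``sigma`` (keys ``system``, ``region``, ``continent``).  Counts are
    NB2 with dispersion ``theta`` (``inf`` gives Poisson).  Returns the
    counts and the realized random effects.
    """
    if design.isna().any().any():
        raise ValueError("design has missing values")
    if not theta > 0:
        raise ValueError("theta must be > 0")
    if any(s < 0 for s in sigma.values()):
        raise ValueError("sigma must be >= 0")
    rng = substream(seed, "richness_counts")
    with np.errstate(divide="ignore"):  # zero area -> -inf, reported below
        eta = np.log(design["area_km2"].to_numpy(dtype=float)) + intercept
    for name, b in beta.items():
        eta = eta + b * design[name].to_numpy(dtype=float)
    effects = {}
    for level, col in (("continent", "continent_id"), ("region", "region_id"), ("system", "system_id")):
        sd = float(sigma.get(level, 0.0))
        groups = design[col].astype(str)
        levels = sorted(groups.unique())
        u = rng.normal(0.0, sd, len(levels)) if sd > 0 else np.zeros(len(levels))
        effects[level] = dict(zip(levels, u))
        eta = eta + groups.map(effects[level]).to_numpy(dtype=float)
    if not np.all(np.isfinite(eta)):
        bad = design.index[~np.isfinite(eta)][0]
        raise ValueError(f"non-finite linear predictor at row {bad!r}")
    mu = np.exp(eta)
    if np.isinf(theta):
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(theta, mu / theta)
        counts = rng.poisson(lam)
    return pd.Series(counts, index=design.index, name="count"), effects


def random_design(
    n_mountains: int,
    predictors: list[str],
    seed: int,
    n_system: int | None = None,
    n_region: int | None = None,
    n_continent: int | None = None,
    area_range: tuple = (50.0, 5000.0),
) -> pd.DataFrame:
    """Random predictor table with a nested hierarchy (testing aid).

    Predictors are standard-normal; areas log-uniform; systems nest in
    regions nest in continents by index arithmetic.
    """
    rng = substream(seed, "design")
    n_system = n_system or max(5, n_mountains // 10)
    n_region = n_region or max(5, n_system // 4)
    n_continent = n_continent or max(5, n_region // 2)
    sys_idx = rng.integers(n_system, size=n_mountains)
    df = pd.DataFrame(index=[f"M{i + 1:05d}" for i in range(n_mountains)])
    df.index.name = "mountain_id"
    df["system_id"] = [f"SY{s + 1:03d}" for s in sys_idx]
    reg_idx = sys_idx * n_region // n_system
    con_idx = reg_idx * n_continent // n_region
    df["region_id"] = [f"RG{r + 1:03d}" for r in reg_idx]
    df["continent_id"] = [f"CT{c + 1:02d}" for c in con_idx]
    lo, hi = np.log(area_range[0]), np.log(area_range[1])
    df["area_km2"] = np.exp(lo + (hi - lo) * rng.random(n_mountains))
    for p in predictors:
        df[p] = rng.standard_normal(n_mountains)
    return df


# ---------------------------------------------------------------------------- I/O


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write every layer in the formats the pipeline reads (text + NetCDF)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_geojson(world.realms, out / "realms.geojson")
    write_geojson(
        (
            {
                "mountain_id": m.mountain_id,
                "system_id": m.system_id,
                "region_id": m.region_id,
                "continent_id": m.continent_id,
                "area_km2": m.area_km2,
                "elev_min": m.elev_min,
                "elev_max": m.elev_max,
                "geometry": m.polygon,
            }
            for m in world.mountains
        ),
        out / "mountains.geojson",
    )
    write_geojson(
        (
            {
                "species_id": sp.species_id,
                "taxon_class": sp.taxon_class,
                "geometry": sp.native_polygons,
            }
            for sp in world.species
            if sp.native_polygons is not None
        ),
        out / "ranges.geojson",
    )
    write_geojson(
        (
            {
                "pa_id": p.pa_id,
                "status": p.status,
                "iucn_cat": p.iucn_category if p.iucn_category is not None else "Not Reported",
                "geometry": p.polygon,
            }
            for p in world.pas
        ),
        out / "pas.geojson",
    )
    for name, df in (("cities", world.cities), ("ports", world.ports)):
        write_geojson(
            (
                {**{k: row[k] for k in df.columns if k not in ("lon", "lat")},
                 "geometry": shapely.points(row["lon"], row["lat"])}
                for _, row in df.iterrows()
            ),
            out / f"{name}.geojson",
        )
    occ = world.occurrences.rename(
        columns={"lon": "decimalLongitude", "lat": "decimalLatitude"}
    )
    occ.to_csv(out / "occurrences.csv", index=False)
    world.dem.write_ascii(out / "dem.asc")
    for name, rast in world.predictor_rasters.items():
        rast.write_ascii(out / f"{name}.asc")
    world.climate_series.to_netcdf(out / "climate_tmin.nc", engine="scipy")

    truth = world.truth
    payload = {
        "alien_flags": {k: bool(v) for k, v in truth.alien_flags.items()},
        "record_mountain": {
            k: (None if v is None else v) for k, v in truth.record_mountain.items()
        },
        "geometry_class": truth.geometry_class,
        "beta": truth.beta,
        "theta": truth.theta,
        "sigma": truth.sigma,
        "flow": truth.flow.to_dict() if truth.flow is not None else None,
        "richness": truth.richness.reset_index().to_dict(orient="list")
        if truth.richness is not None
        else None,
    }
    (out / "truth.json").write_text(json.dumps(payload, sort_keys=True))
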