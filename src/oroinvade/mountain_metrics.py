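"""Mountain-level predictors: terrain roughness, geometry classes,
gradient-based climate velocity and zonal/distance extractions.

Roughness is the 3×3 max−min window; geometry follows the
hourglass → pyramid → inverse-pyramid → diamond rule order on moment
skewness and the dip statistic; climate velocity is the per-cell ratio
of the temporal trend of annual means to the magnitude of the spatial
gradient of the period climatology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import skew

from .dip import dip_statistic, dip_pvalue
from .geoio import KM_PER_DEG_LAT, point_to_geom_km
from .raster import Raster, zonal_mask, zonal_mean

__all__ = [
    "terrain_roughness",
    "classify_geometry",
    "GeometryClass",
    "gvocc",
    "VelocityField",
    "extract_predictors",
]

#: spatial gradients below this (°C/km) make velocity undefined, not infinite
GRADIENT_EPS = 1e-6


def terrain_roughness(dem: Raster) -> Raster:
    """Max − min elevation over each cell's 3×3 neighborhood.

    Edge cells use their available neighbors; a nodata cell stays nodata
    (nodata neighbors are simply unavailable).
    """
    data = dem.data
    if not np.any(np.isfinite(data)):
        raise ValueError("all-nodata DEM")
    nan = ~np.isfinite(data)
    hi = ndimage.maximum_filter(np.where(nan, -np.inf, data), size=3, mode="nearest")
    lo = ndimage.minimum_filter(np.where(nan, np.inf, data), size=3, mode="nearest")
    rough = hi - lo
    rough[nan] = np.nan
    return dem.copy_with(rough)


@dataclass
class GeometryClass:
    mountain_id: str
    skewness: float
    dip: float
    p_dip: float
    geometry: str  # pyramid | inverse_pyramid | diamond | hourglass


def classify_geometry(
    elevations,
    mountain_id: str = "",
    dip_threshold: float = 0.01,
    p_threshold: float = 0.05,
    skew_threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 987654321,
) -> GeometryClass:
    """Classify a mountain's elevation sample into one of four geometries.

    Rule order: (1) hourglass when dip > 0.01 and the dip test rejects
    unimodality at p < 0.05, irrespective of skewness; otherwise
    (2) pyramid when moment skewness ≥ 0.5, (3) inverse pyramid when
    ≤ −0.5, (4) diamond in between.
    """
    x = np.asarray(elevations, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 30:
        raise ValueError(
            f"classification refused for {mountain_id or 'sample'}: "
            f"{x.size} cells < 30 minimum"
        )
    g1 = float(skew(x, bias=True))  # moment coefficient of skewness
    d = dip_statistic(x)
    p = dip_pvalue(d, x.size, n_boot=n_boot, seed=seed)
    if d > dip_threshold and p < p_threshold:
        cls = "hourglass"
    elif g1 >= skew_threshold:
        cls = "pyramid"
    elif g1 <= -skew_threshold:
        cls = "inverse_pyramid"
    else:
        cls = "diamond"
    return GeometryClass(mountain_id=mountain_id, skewness=g1, dip=d, p_dip=p, geometry=cls)


@dataclass
class VelocityField:
    trend: Raster  # °C/yr
    gradient: Raster  # °C/km
    velocity: Raster  # km/yr; NaN where gradient < eps


def gvocc(climate, eps: float = GRADIENT_EPS) -> VelocityField:
    """Gradient-based velocity of climate change from a monthly stack.

    ``climate`` is an xarray DataArray (time, y, x) of monthly values
    spanning ≥ 10 years.  Per cell: the temporal trend is the OLS slope
    of annual means against year; the spatial gradient is the magnitude
    of the lon/lat gradient of the full-period mean field with
    latitude-corrected cell widths; velocity = trend / gradient, flagged
    undefined (NaN) where the gradient is below ``eps``.
    """
    time = pd.DatetimeIndex(climate["time"].values)
    years = np.unique(time.year)
    if len(years) < 10:
        raise ValueError("climate stack must span at least 10 years")
    data = np.asarray(climate.values, dtype=float)
    year_of = time.year.to_numpy()
    annual = np.stack([data[year_of == y].mean(axis=0) for y in years])

    t = years.astype(float)
    t = t - t.mean()
    denom = (t**2).sum()
    slope = np.tensordot(t, annual - annual.mean(axis=0), axes=(0, 0)) / denom  # °C/yr

    lat = np.asarray(climate["y"].values, dtype=float)
    lon = np.asarray(climate["x"].values, dtype=float)
    res = float(abs(lat[1] - lat[0])) if len(lat) > 1 else float(abs(lon[1] - lon[0]))
    clim = annual.mean(axis=0)
    dy_km = res * KM_PER_DEG_LAT
    dx_km = res * KM_PER_DEG_LAT * np.cos(np.deg2rad(lat))  # per row
    gy = np.gradient(clim, axis=0) / dy_km
    gx = np.gradient(clim, axis=1) / dx_km[:, None]
    grad = np.hypot(gx, gy)

    with np.errstate(divide="ignore", invalid="ignore"):
        vel = np.where(grad >= eps, slope / grad, np.nan)

    if len(lat) > 1 and lat[0] < lat[-1]:
        raise ValueError("climate stack must be north-up (descending latitude)")
    x0 = lon[0] - res / 2
    y0 = lat[0] + res / 2
    mk = lambda d: Raster(d, x0, y0, res)
    return VelocityField(trend=mk(slope), gradient=mk(grad), velocity=mk(vel))


def extract_predictors(
    mountains,
    rasters: dict,
    cities: pd.DataFrame,
    ports: pd.DataFrame,
    velocity: VelocityField | None = None,
    geometry_classes: dict | None = None,
    roughness: Raster | None = None,
    min_defined_fraction: float = 0.25,
) -> pd.DataFrame:
    """Assemble the per-mountain predictor table.

    Zonal means (center rule) for raster layers, great-circle minimum
    distances to cities and ports, elevation range from the mountain
    attributes, plus the geometry class and mean climate velocity when
    supplied.  Missingness is explicit (NaN) and mountains whose
    velocity field is defined on fewer than ``min_defined_fraction`` of
    their cells are flagged.
    """
    rows = []
    for m in mountains:
        row = {
            "mountain_id": m.mountain_id,
            "system_id": m.system_id,
            "region_id": m.region_id,
            "continent_id": m.continent_id,
            "area_km2": m.area_km2,
            "elev_range": m.elev_max - m.elev_min,
        }
        for name, rast in rasters.items():
            row[name] = zonal_mean(rast, m.polygon)
        if roughness is not None:
            row["roughness"] = zonal_mean(roughness, m.polygon)
        if velocity is not None:
            mask = zonal_mask(velocity.velocity, m.polygon)
            vals = velocity.velocity.data[mask]
            n_cells = vals.size
            defined = vals[np.isfinite(vals)]
            row["gvocc_tmin"] = float(defined.mean()) if defined.size else float("nan")
            row["gvocc_low_coverage"] = bool(
                n_cells == 0 or defined.size < min_defined_fraction * n_cells
            )
        if geometry_classes is not None:
            gc = geometry_classes.get(m.mountain_id)
            row["geometry"] = gc.geometry if isinstance(gc, GeometryClass) else gc
        row["dist_cities"] = (
            min(point_to_geom_km(c.lon, c.lat, m.polygon) for c in cities.itertuples())
            if len(cities)
            else float("nan")
        )
        row["dist_ports"] = (
            min(point_to_geom_km(p.lon, p.lat, m.polygon) for p in ports.itertuples())
            if len(ports)
            else float("nan")
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("mountain_id")
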