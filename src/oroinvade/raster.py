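"""Minimal north-up raster grid with text (ESRI ASCII) persistence.

The deliverable pipeline only needs single-band lon/lat grids; a 2-D
float array plus the grid origin and resolution is sufficient and keeps
all on-disk artifacts plain text.  Climate stacks are handled by
:mod:`oroinvade.synthworld` as NetCDF via xarray.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

__all__ = ["Raster", "zonal_mask", "zonal_mean"]


@dataclass
class Raster:
    """Single-band north-up grid in geographic coordinates.

    ``data[0, 0]`` is the north-west cell; ``x0``/``y0`` are the
    coordinates of the *top-left corner* of that cell; ``res`` is the cell
    size in degrees (square cells).  Nodata is ``NaN``.
    """

    data: np.ndarray
    x0: float
    y0: float
    res: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude and latitude of every cell center (2-D arrays)."""
        nrow, ncol = self.data.shape
        lon = self.x0 + (np.arange(ncol) + 0.5) * self.res
        lat = self.y0 - (np.arange(nrow) + 0.5) * self.res
        return np.meshgrid(lon, lat)

    def copy_with(self, data: np.ndarray) -> "Raster":
        return Raster(np.asarray(data, dtype=float), self.x0, self.y0, self.res)

    # ------------------------------------------------------------------ I/O

    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        """Write as ESRI ASCII grid (plain text)."""
        nrow, ncol = self.data.shape
        yll = self.y0 - nrow * self.res
        header = (
            f"ncols {ncol}\n"
            f"nrows {nrow}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {yll!r}\n"
            f"cellsize {self.res!r}\n"
            f"NODATA_value {nodata!r}\n"
        )
        body = np.where(np.isnan(self.data), nodata, self.data)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = hdr["nodata_value"]
        data[data == nodata] = np.nan
        y0 = hdr["yllcorner"] + hdr["nrows"] * hdr["cellsize"]
        return cls(data, hdr["xllcorner"], y0, hdr["cellsize"])


def zonal_mask(raster: Raster, geom: BaseGeometry) -> np.ndarray:
    """Boolean mask of cells whose *center* falls inside ``geom``.

    Boundary centers count as inside (covers semantics).  Only the cells
    within the geometry's bounding box are tested.
    """
    nrow, ncol = raster.shape
    minx, miny, maxx, maxy = geom.bounds
    j0 = max(0, int(math.floor((minx - raster.x0) / raster.res)) - 1)
    j1 = min(ncol, int(math.ceil((maxx - raster.x0) / raster.res)) + 1)
    i0 = max(0, int(math.floor((raster.y0 - maxy) / raster.res)) - 1)
    i1 = min(nrow, int(math.ceil((raster.y0 - miny) / raster.res)) + 1)
    mask = np.zeros((nrow, ncol), dtype=bool)
    if j0 >= j1 or i0 >= i1:
        return mask
    lon = raster.x0 + (np.arange(j0, j1) + 0.5) * raster.res
    lat = raster.y0 - (np.arange(i0, i1) + 0.5) * raster.res
    lon2, lat2 = np.meshgrid(lon, lat)
    shapely.prepare(geom)
    inside = shapely.contains_xy(geom, lon2.ravel(), lat2.ravel()) | shapely.intersects_xy(
        shapely.boundary(geom), lon2.ravel(), lat2.ravel()
    )
    mask[i0:i1, j0:j1] = inside.reshape(lat2.shape)
    return mask


def zonal_mean(raster: Raster, geom: BaseGeometry) -> float:
    """Mean of defined cell values whose centers fall inside ``geom``.

    ``NaN`` when the geometry captures no cell center or no defined cell.
    """
    mask = zonal_mask(raster, geom)
    vals = raster.data[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())
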