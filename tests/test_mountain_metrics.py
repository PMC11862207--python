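"""Terrain roughness, geometry classification, climate velocity, zonal extraction."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from oroinvade.mountain_metrics import (
    classify_geometry,
    extract_predictors,
    gvocc,
    terrain_roughness,
)
from oroinvade.raster import Raster, zonal_mask, zonal_mean
from oroinvade.synthworld import Mountain, simulate_climate_series


def mk_mountain(mid, geom, area=100.0, elev_min=100.0, elev_max=900.0):
    return Mountain(mid, geom, "S1", "R1", "C1", area, elev_min, elev_max)


class TestRoughness:
    def test_constant_raster_zero(self):
        dem = Raster(np.full((10, 10), 250.0), 0, 10, 1.0)
        assert np.all(terrain_roughness(dem).data == 0.0)

    def test_center_of_1_to_9_window(self):
        dem = Raster(np.arange(1.0, 10.0).reshape(3, 3), 0, 3, 1.0)
        assert terrain_roughness(dem).data[1, 1] == 8.0

    def test_brute_force_oracle(self, rng):
        dem = Raster(rng.random((50, 50)) * 2000, 0, 50, 1.0)
        rough = terrain_roughness(dem).data
        for i in range(50):
            for j in range(50):
                w = dem.data[max(0, i - 1) : i + 2, max(0, j - 1) : j + 2]
                assert rough[i, j] == w.max() - w.min()

    def test_nodata_propagates(self):
        data = np.ones((5, 5))
        data[2, 2] = np.nan
        rough = terrain_roughness(Raster(data, 0, 5, 1.0)).data
        assert np.isnan(rough[2, 2])
        assert rough[0, 0] == 0.0  # neighbors of the hole are unaffected (constant field)

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError):
            terrain_roughness(Raster(np.full((4, 4), np.nan), 0, 4, 1.0))

    def test_translation_invariance_and_scaling(self, rng):
        dem = Raster(rng.random((20, 20)) * 100, 0, 20, 1.0)
        base = terrain_roughness(dem).data
        shifted = terrain_roughness(dem.copy_with(dem.data + 555.0)).data
        scaled = terrain_roughness(dem.copy_with(dem.data * 3.0)).data
        assert np.allclose(base, shifted)
        assert np.allclose(scaled, 3.0 * base)


class TestGeometryClassifier:
    def test_right_skewed_unimodal_pyramid(self, rng):
        x = rng.beta(1.2, 5.0, 500) * 2000 + 300
        gc = classify_geometry(x, "m")
        assert gc.geometry == "pyramid"
        assert gc.skewness >= 0.5

    def test_left_skewed_inverse_pyramid(self, rng):
        x = rng.beta(5.0, 1.2, 500) * 2000 + 300
        assert classify_geometry(x, "m").geometry == "inverse_pyramid"

    def test_symmetric_unimodal_diamond(self, rng):
        x = rng.beta(5.0, 5.0, 500) * 2000 + 300
        gc = classify_geometry(x, "m")
        assert gc.geometry == "diamond"
        assert abs(gc.skewness) < 0.5

    def test_hourglass_overrides_skew(self, rng):
        # bimodal but globally right-skewed: hourglass must win
        x = np.concatenate([rng.normal(0.1, 0.03, 400), rng.normal(0.75, 0.10, 200)])
        gc = classify_geometry(x * 2500 + 500, "m")
        assert gc.dip > 0.01 and gc.p_dip < 0.05
        assert gc.geometry == "hourglass"

    def test_small_sample_refused(self, rng):
        with pytest.raises(ValueError, match="< 30"):
            classify_geometry(rng.random(20), "tiny")

    def test_exactly_one_class(self, rng):
        for _ in range(20):
            x = rng.normal(size=100)
            gc = classify_geometry(x, "m")
            assert gc.geometry in {"pyramid", "inverse_pyramid", "diamond", "hourglass"}


class TestGvocc:
    def _template(self, n=15):
        return Raster(np.zeros((n, n)), 0, n, 1.0)

    def test_closed_form_two_km_per_year(self):
        clim = simulate_climate_series(
            self._template(), trend=0.02, spatial_gradient=0.01, noise_sd=0.0, years=15, seed=0
        )
        v = gvocc(clim).velocity.data
        assert np.all(np.isfinite(v))
        assert np.abs(v - 2.0).max() < 1e-6

    def test_zero_trend_zero_velocity(self):
        clim = simulate_climate_series(
            self._template(), trend=0.0, spatial_gradient=0.01, noise_sd=0.0, years=12, seed=0
        )
        v = gvocc(clim).velocity.data
        assert np.abs(v).max() < 1e-12

    def test_flat_field_undefined(self):
        clim = simulate_climate_series(
            self._template(), trend=0.02, spatial_gradient=0.0, noise_sd=0.0, years=12, seed=0
        )
        v = gvocc(clim).velocity.data
        assert np.all(np.isnan(v))

    def test_noisy_trend_within_3se(self):
        years, noise = 40, 0.25
        clim = simulate_climate_series(
            self._template(8), trend=0.02, spatial_gradient=0.05, noise_sd=noise, years=years, seed=3
        )
        field = gvocc(clim)
        t = np.arange(years, dtype=float)
        tc = t - t.mean()
        se = (noise / np.sqrt(12)) / np.sqrt((tc**2).sum())
        # max over 64 cells: allow 4 SE (expected max of 64 normals ~ 2.7 SE)
        assert np.abs(field.trend.data - 0.02).max() < 4.0 * se

    def test_sign_follows_trend(self):
        clim = simulate_climate_series(
            self._template(), trend=-0.03, spatial_gradient=0.01, noise_sd=0.0, years=12, seed=0
        )
        v = gvocc(clim).velocity.data
        assert np.all(v < 0)

    def test_too_short_rejected(self):
        clim = simulate_climate_series(
            self._template(), trend=0.0, spatial_gradient=0.01, noise_sd=0.0, years=5, seed=0
        )
        with pytest.raises(ValueError, match="10 years"):
            gvocc(clim)


class TestExtractPredictors:
    def test_constant_raster_zonal_mean(self):
        rast = Raster(np.full((20, 20), 7.5), 0, 20, 1.0)
        m = mk_mountain("M1", box(2, 2, 8, 8))
        out = extract_predictors([m], {"layer": rast}, pd.DataFrame(columns=["lon", "lat"]),
                                 pd.DataFrame(columns=["lon", "lat"]))
        assert out.loc["M1", "layer"] == pytest.approx(7.5)

    def test_city_inside_polygon_distance_zero(self):
        m = mk_mountain("M1", box(2, 2, 8, 8))
        cities = pd.DataFrame({"lon": [5.0], "lat": [5.0]})
        ports = pd.DataFrame({"lon": [50.0], "lat": [50.0]})
        out = extract_predictors([m], {}, cities, ports)
        assert out.loc["M1", "dist_cities"] == 0.0
        assert out.loc["M1", "dist_ports"] > 0.0

    def test_elev_range_from_attributes(self):
        m = mk_mountain("M1", box(0, 0, 2, 2), elev_min=200.0, elev_max=1700.0)
        out = extract_predictors([m], {}, pd.DataFrame(columns=["lon", "lat"]),
                                 pd.DataFrame(columns=["lon", "lat"]))
        assert out.loc["M1", "elev_range"] == 1500.0

    def test_zonal_oracle_equivalence(self, rng):
        rast = Raster(rng.random((30, 30)), 0, 30, 1.0)
        polys = [shapely.points(x, y).buffer(3.0, quad_segs=4)
                 for x, y in zip(rng.uniform(5, 25, 6), rng.uniform(5, 25, 6))]
        mountains = [mk_mountain(f"M{i}", p) for i, p in enumerate(polys)]
        out = extract_predictors(mountains, {"layer": rast}, pd.DataFrame(columns=["lon", "lat"]),
                                 pd.DataFrame(columns=["lon", "lat"]))
        lon2, lat2 = rast.cell_centers()
        for m in mountains:
            vals = [rast.data[i, j] for i in range(30) for j in range(30)
                    if m.polygon.covers(shapely.points(lon2[i, j], lat2[i, j]))]
            assert out.loc[m.mountain_id, "layer"] == pytest.approx(np.mean(vals), abs=1e-9)

    def test_no_cells_gives_nan(self):
        rast = Raster(np.ones((5, 5)), 0, 5, 1.0)
        m = mk_mountain("M1", box(100, 100, 101, 101))
        out = extract_predictors([m], {"layer": rast}, pd.DataFrame(columns=["lon", "lat"]),
                                 pd.DataFrame(columns=["lon", "lat"]))
        assert np.isnan(out.loc["M1", "layer"])

    def test_low_coverage_flagged(self):
        from oroinvade.mountain_metrics import VelocityField

        vel_data = np.full((10, 10), np.nan)
        vel_data[0, 0] = 1.0
        vf = VelocityField(
            trend=Raster(np.zeros((10, 10)), 0, 10, 1.0),
            gradient=Raster(np.ones((10, 10)), 0, 10, 1.0),
            velocity=Raster(vel_data, 0, 10, 1.0),
        )
        m = mk_mountain("M1", box(1, 1, 9, 9))
        out = extract_predictors([m], {}, pd.DataFrame(columns=["lon", "lat"]),
                                 pd.DataFrame(columns=["lon", "lat"]), velocity=vf)
        assert bool(out.loc["M1", "gvocc_low_coverage"])
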