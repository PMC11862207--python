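"""Synthetic world generator: determinism, invariants, generative laws."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oroinvade.raster import Raster
from oroinvade.synthworld import (
    WorldConfig,
    generate_world,
    random_design,
    simulate_climate_series,
    simulate_occurrences,
    simulate_richness_counts,
    write_world,
)

SMALL = dict(
    n_mountains=12,
    n_species_pool=30,
    raster_resolution=0.5,
    grid_extent=(0.0, 0.0, 20.0, 20.0),
    climate_years=10,
)


def _gen(seed=5, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_world(WorldConfig(seed=seed, **{**SMALL, **kw}))


class TestConfig:
    def test_bad_counts(self):
        with pytest.raises(ValueError):
            WorldConfig(n_realms=0).validate()

    def test_bad_weights(self):
        with pytest.raises(ValueError):
            WorldConfig(taxon_class_weights={"fish": 0.5, "bird": 0.4}).validate()

    def test_degenerate_extent(self):
        with pytest.raises(ValueError):
            WorldConfig(grid_extent=(0, 0, 0, 10)).validate()


class TestGenerateWorld:
    def test_seed_determinism_byte_identical(self, tmp_path):
        w1, w2 = _gen(seed=9), _gen(seed=9)
        write_world(w1, tmp_path / "a")
        write_world(w2, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_single_realm_forces_all_native_there(self):
        w = _gen(seed=2, n_realms=1)
        assert all(s.native_realms == {"R01"} for s in w.species)
        assert w.truth.flow.shape == (1, 1)

    def test_mountains_pairwise_disjoint(self):
        w = _gen(seed=7, n_mountains=20)
        polys = [m.polygon for m in w.mountains]
        assert len(polys) == 20
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                assert polys[i].intersection(polys[j]).area == 0.0

    def test_realms_tile_extent(self):
        w = _gen(seed=4)
        total = sum(r["geometry"].area for r in w.realms)
        assert total == pytest.approx(400.0, rel=1e-9)

    def test_dem_positive_on_mountains(self):
        w = _gen(seed=4)
        from oroinvade.raster import zonal_mask

        for m in w.mountains:
            vals = w.dem.data[zonal_mask(w.dem, m.polygon)]
            assert (vals > 0).all()

    def test_hierarchy_assigned(self):
        w = _gen(seed=4)
        for m in w.mountains:
            assert m.system_id and m.region_id and m.continent_id


class TestOccurrences:
    def test_alien_fraction_zero(self):
        w = _gen(seed=6)
        occ = simulate_occurrences(w, 0.0, 5.0, seed=1)
        assert len(occ) > 0
        assert not w.truth.alien_flags.any()

    def test_alien_fraction_one(self):
        w = _gen(seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            occ = simulate_occurrences(w, 1.0, 5.0, seed=1)
        assert w.truth.alien_flags.all()
        # no record inside its own native polygon
        by_sp = {s.species_id: s for s in w.species}
        import shapely

        for _, row in occ.iterrows():
            native = by_sp[row.species_id].native_polygons
            assert not native.covers(shapely.points(row.lon, row.lat))

    def test_mixture_within_binomial_ci(self):
        w = _gen(seed=6, n_species_pool=100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            occ = simulate_occurrences(w, 0.5, 100.0, seed=2)
        n = len(occ)
        assert n == pytest.approx(10000, rel=0.25)
        k = int(w.truth.alien_flags.sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= k <= hi

    def test_mixture_conservation(self):
        w = _gen(seed=6)
        occ = simulate_occurrences(w, 0.3, 10.0, seed=3)
        flags = w.truth.alien_flags
        assert int(flags.sum()) + int((~flags).sum()) == len(occ)

    def test_bad_fraction(self):
        w = _gen(seed=6)
        with pytest.raises(ValueError):
            simulate_occurrences(w, 1.5, 5.0, seed=1)

    def test_records_inside_extent(self):
        w = _gen(seed=8)
        x0, y0, x1, y1 = w.config.grid_extent
        assert w.occurrences["lon"].between(x0, x1).all()
        assert w.occurrences["lat"].between(y0, y1).all()


class TestRichnessCounts:
    def test_poisson_limit_mean_matches_area(self):
        design = random_design(5000, [], seed=1, area_range=(100.0, 100.0))
        counts, _ = simulate_richness_counts(design, {}, theta=np.inf, sigma={}, seed=2)
        # eta = log(100) -> mean 100; LLN at n=5000
        assert counts.mean() == pytest.approx(100.0, rel=0.02)

    def test_nb_mean_variance_relation(self):
        theta = 2.0
        design = random_design(40000, [], seed=3, area_range=(50.0, 50.0))
        counts, _ = simulate_richness_counts(design, {}, theta=theta, sigma={}, seed=4)
        mu = counts.mean()
        expected_var = mu + mu**2 / theta
        assert counts.var() == pytest.approx(expected_var, rel=0.1)

    def test_beta_monotonicity(self):
        design = random_design(2000, ["x"], seed=5)
        c1, _ = simulate_richness_counts(design, {"x": 0.3}, theta=np.inf, sigma={}, seed=6)
        c2, _ = simulate_richness_counts(design, {"x": 0.6}, theta=np.inf, sigma={}, seed=6)
        hi_x = design["x"] > 1.0
        # doubling beta raises mean counts where the predictor is large
        assert c2[hi_x].mean() > c1[hi_x].mean()

    def test_system_icc_exceeds_shuffled_baseline(self, rng):
        design = random_design(2000, [], seed=7)
        counts, _ = simulate_richness_counts(
            design, {}, theta=np.inf, sigma={"system": 1.0}, seed=8
        )
        logc = np.log1p(counts.to_numpy(dtype=float))
        groups = design["system_id"].to_numpy()

        def between_group_var(g):
            s = pd.Series(logc).groupby(g).mean()
            return float(s.var())

        observed = between_group_var(groups)
        null = [between_group_var(rng.permutation(groups)) for _ in range(200)]
        assert observed > np.quantile(null, 0.99)

    def test_nonfinite_eta_names_row(self):
        design = random_design(10, ["x"], seed=9)
        design.loc[design.index[3], "area_km2"] = 0.0  # log -> -inf
        with pytest.raises(ValueError, match=design.index[3]):
            simulate_richness_counts(design, {"x": 0.1}, theta=2.0, sigma={}, seed=1)

    def test_missing_design_rejected(self):
        design = random_design(10, ["x"], seed=9)
        design.loc[design.index[0], "x"] = np.nan
        with pytest.raises(ValueError):
            simulate_richness_counts(design, {"x": 0.1}, theta=2.0, sigma={}, seed=1)


class TestClimate:
    def test_closed_form_construction(self):
        tmpl = Raster(np.zeros((10, 10)), 0, 10, 1.0)
        clim = simulate_climate_series(tmpl, trend=0.02, spatial_gradient=0.01, noise_sd=0.0, years=12, seed=0)
        # flat in x, linear trend in time
        d = clim.values
        assert np.allclose(d[:, :, 0], d[:, :, -1])
        first, last = d[0], d[-1]
        months = d.shape[0]
        assert np.allclose(last - first, 0.02 * (months - 1) / 12.0)

    def test_zero_trend_flat_in_time(self):
        tmpl = Raster(np.zeros((5, 5)), 0, 5, 1.0)
        clim = simulate_climate_series(tmpl, trend=0.0, spatial_gradient=0.05, noise_sd=0.0, years=5, seed=0)
        assert np.allclose(clim.values.std(axis=0), 0.0)

    def test_noisy_slope_within_3se(self):
        tmpl = Raster(np.zeros((6, 6)), 0, 6, 1.0)
        years, noise, trend = 40, 0.3, 0.02
        clim = simulate_climate_series(tmpl, trend=trend, spatial_gradient=0.0, noise_sd=noise, years=years, seed=5)
        t = np.arange(years, dtype=float)
        annual = clim.values.reshape(years, 12, 6, 6).mean(axis=1)
        tc = t - t.mean()
        denom = (tc**2).sum()
        slopes = np.tensordot(tc, annual - annual.mean(axis=0), axes=(0, 0)) / denom
        se = (noise / np.sqrt(12)) / np.sqrt(denom)
        assert np.all(np.abs(slopes - trend) < 3.5 * se)

    def test_years_minimum(self):
        tmpl = Raster(np.zeros((5, 5)), 0, 5, 1.0)
        with pytest.raises(ValueError):
            simulate_climate_series(tmpl, years=1)
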