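"""Collinearity screen, standardization, NB GLMM engine and refits."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from oroinvade.invasion_glmm import (
    ModelSpec,
    back_transform,
    collinearity_screen,
    fit_nb_glmm,
    sensitivity_refits,
    standardize,
    taxon_models,
)
from oroinvade.nbglmm import fit_nb_glmm_arrays
from oroinvade.synthworld import random_design, simulate_richness_counts

TRUE_BETA = np.array([0.3, -0.2, 0.1, 0.0, 0.5, -0.4])
PREDICTORS = [f"x{i}" for i in range(len(TRUE_BETA))]


def sim_data(n=1500, theta=2.0, sigma=None, seed=0, beta=TRUE_BETA):
    design = random_design(n, PREDICTORS, seed=seed)
    counts, _ = simulate_richness_counts(
        design, dict(zip(PREDICTORS, beta)), theta=theta, sigma=sigma or {}, seed=seed + 1
    )
    design["count"] = counts
    return design


def base_spec(**kw):
    defaults = dict(response="count", predictors=tuple(PREDICTORS), geometry_column=None,
                    standardize=False, min_rows_per_effect=5)
    defaults.update(kw)
    return ModelSpec(**defaults)


class TestCollinearityScreen:
    def test_duplicate_column_drops_one(self, rng):
        df = pd.DataFrame({"a": rng.random(100)})
        df["b"] = df["a"]
        df["c"] = rng.random(100)
        retained, _ = collinearity_screen(df)
        assert len({"a", "b"} & set(retained)) == 1
        assert "c" in retained

    def test_r_069_both_retained(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        target = 0.69
        y = target * x + np.sqrt(1 - target**2) * rng.standard_normal(n)
        df = pd.DataFrame({"a": x, "b": y})
        r = df.corr().iloc[0, 1]
        assert abs(r) < 0.7  # construction sanity
        retained, _ = collinearity_screen(df)
        assert set(retained) == {"a", "b"}

    def test_independent_predictors_none_removed(self, rng):
        df = pd.DataFrame(rng.standard_normal((1000, 6)), columns=list("abcdef"))
        retained, _ = collinearity_screen(df)
        assert set(retained) == set("abcdef")

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            collinearity_screen(pd.DataFrame({"a": [1.0]}))


class TestStandardize:
    def test_simple_column(self):
        scaled, scaler = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(scaled["x"], [-1.0, 0.0, 1.0])  # sample SD convention
        assert scaler["x"] == (2.0, 1.0)

    def test_idempotent_within_tolerance(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(500)})
        once, _ = standardize(df)
        twice, _ = standardize(once)
        assert np.abs(once["x"] - twice["x"]).max() < 1e-9

    def test_round_trip(self, rng):
        df = pd.DataFrame({"x": rng.random(100) * 7 + 3, "y": rng.random(100)})
        scaled, scaler = standardize(df)
        assert np.allclose(back_transform(scaled, scaler), df, atol=1e-12)

    def test_zero_sd_named(self):
        with pytest.raises(ValueError, match="flat"):
            standardize(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))

    def test_moments(self, rng):
        scaled, _ = standardize(pd.DataFrame({"x": rng.random(321)}))
        assert abs(scaled["x"].mean()) < 1e-9
        assert scaled["x"].std(ddof=1) == pytest.approx(1.0)

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50).filter(
            lambda v: np.std(v, ddof=1) > 1e-6
        )
    )
    def test_round_trip_property(self, values):
        df = pd.DataFrame({"x": values})
        scaled, scaler = standardize(df)
        restored = back_transform(scaled, scaler)
        assert np.allclose(restored["x"], df["x"], rtol=1e-9, atol=1e-6)


class TestFitAgainstOracle:
    def test_sigma_zero_matches_plain_nb_regression(self):
        data = sim_data(n=2000, sigma={}, seed=3)
        fit = fit_nb_glmm(base_spec(), data)
        X = np.column_stack([np.ones(len(data))] + [data[p] for p in PREDICTORS])
        oracle = sm.NegativeBinomial(
            data["count"].to_numpy(), X, offset=np.log(data["area_km2"].to_numpy())
        ).fit(disp=0)
        diff = np.abs(fit.coef["estimate"].to_numpy() - oracle.params[:-1])
        assert diff.max() < 0.02

    def test_offset_identity(self):
        data = sim_data(n=800, sigma={"system": 0.3}, seed=4)
        fit1 = fit_nb_glmm(base_spec(), data)
        doubled = data.copy()
        doubled["area_km2"] = 2.0 * doubled["area_km2"]
        fit2 = fit_nb_glmm(base_spec(), doubled)
        c1 = fit1.coef.set_index("term")["estimate"]
        c2 = fit2.coef.set_index("term")["estimate"]
        assert c2["(intercept)"] - c1["(intercept)"] == pytest.approx(-np.log(2), abs=1e-6)
        slopes = [t for t in c1.index if t != "(intercept)"]
        assert np.abs(c1[slopes] - c2[slopes]).max() < 1e-6

    def test_scaling_equivariance_of_standardized_fit(self):
        data = sim_data(n=800, sigma={}, seed=5)
        spec = base_spec(standardize=True)
        fit1 = fit_nb_glmm(spec, data)
        rescaled = data.copy()
        rescaled["x0"] = rescaled["x0"] * 123.0
        fit2 = fit_nb_glmm(spec, rescaled)
        a = fit1.coef.set_index("term")["estimate"]
        b = fit2.coef.set_index("term")["estimate"]
        assert np.abs(a - b).max() < 1e-8

    def test_likelihood_ascent_trace(self):
        data = sim_data(n=500, sigma={"system": 0.3}, seed=6)
        fit = fit_nb_glmm(base_spec(), data)
        trace = np.array(fit.raw.objective_trace)
        assert np.all(np.diff(trace) >= 0.0)  # best-so-far never decreases

    def test_poisson_limit(self):
        # simulate near-Poisson data; fitted theta should be large and slopes
        # should approach the Poisson-oracle fit
        data = sim_data(n=2000, theta=np.inf, sigma={}, seed=7)
        fit = fit_nb_glmm(base_spec(), data)
        assert fit.theta > 5.0
        X = np.column_stack([np.ones(len(data))] + [data[p] for p in PREDICTORS])
        oracle = sm.GLM(
            data["count"].to_numpy(), X, family=sm.families.Poisson(),
            offset=np.log(data["area_km2"].to_numpy()),
        ).fit()
        assert np.abs(fit.coef["estimate"].to_numpy() - oracle.params).max() < 0.02

    def test_complete_cases_counted(self):
        data = sim_data(n=600, sigma={}, seed=8)
        data.loc[data.index[:25], "x0"] = np.nan
        fit = fit_nb_glmm(base_spec(), data)
        assert fit.n_dropped == 25
        assert fit.n_obs == 575

    def test_geometry_baseline_excluded(self):
        data = sim_data(n=900, sigma={}, seed=9)
        rng = np.random.default_rng(1)
        data["geometry"] = rng.choice(
            ["diamond", "pyramid", "inverse_pyramid", "hourglass"], len(data)
        )
        fit = fit_nb_glmm(base_spec(geometry_column="geometry"), data)
        terms = set(fit.coef["term"])
        assert "geometry[pyramid]" in terms
        assert "geometry[diamond]" not in terms  # reference level

    def test_group_count_precondition(self):
        data = sim_data(n=200, sigma={}, seed=10)
        data["continent_id"] = "C1"  # single group
        with pytest.raises(ValueError, match="continent"):
            fit_nb_glmm(base_spec(), data)


class TestTaxonModels:
    def test_absent_class_refused(self):
        data = sim_data(n=400, sigma={}, seed=11)
        data["count_fish"] = 0
        with pytest.raises(ValueError, match="absent"):
            taxon_models(base_spec(), data, ["fish"])

    def test_class_identical_to_full_data(self):
        data = sim_data(n=900, sigma={}, seed=12)
        data = data[data["count"] > 0].copy()
        data["count_bird"] = data["count"]
        full = fit_nb_glmm(base_spec(), data)
        per = taxon_models(base_spec(), data, ["bird"])["bird"]
        a = full.coef.set_index("term")["estimate"]
        b = per.coef.set_index("term")["estimate"]
        assert np.abs(a - b).max() < 1e-6

    def test_opposite_signs_recovered(self):
        d1 = sim_data(n=1200, sigma={}, seed=13, beta=TRUE_BETA).assign(
            count_fish=lambda d: d["count"]
        )
        d2 = sim_data(n=1200, sigma={}, seed=14, beta=-TRUE_BETA).assign(
            count_bird=lambda d: d["count"]
        )
        f1 = taxon_models(base_spec(), d1, ["fish"])["fish"]
        f2 = taxon_models(base_spec(), d2, ["bird"])["bird"]
        s1 = f1.coef.set_index("term").loc["x4", "estimate"]  # strongest effect (0.5)
        s2 = f2.coef.set_index("term").loc["x4", "estimate"]
        assert s1 > 0 > s2


class TestSensitivity:
    def test_full_subsets_stability_one(self):
        data = sim_data(n=600, sigma={}, seed=15)
        out = sensitivity_refits(base_spec(), data, rules=["full", "full"], seed=1)
        assert (out["sign_stability"] == 1.0).all()

    def test_strong_effect_sign_stable(self):
        beta = np.array([0.6, 0.0, 0.0, 0.0, 0.0, 0.0])
        data = sim_data(n=2000, sigma={}, seed=16, beta=beta)
        out = sensitivity_refits(base_spec(), data, rules=["random80x10"], seed=2)
        row = out.set_index("term").loc["x0"]
        assert row["sign_stability"] == 1.0
        assert row["significance_fraction"] == 1.0

    def test_failed_subset_recorded(self):
        data = sim_data(n=600, sigma={}, seed=17)
        tiny = ("tiny", data.index[:10])
        out = sensitivity_refits(base_spec(), data, rules=["full", tiny], seed=3)
        assert out["n_subsets_failed"].iloc[0] == 1
        assert out.attrs["failures"][0]["subset"] == "tiny"
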