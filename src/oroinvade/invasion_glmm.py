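"""Cross-taxon and taxon-specific NB mixed models of alien richness.

Wraps the Laplace engine with the modelling protocol: collinearity
screening at |r| > 0.7, standardization to mean 0 / SD 1, diamond as the
geometry reference level, log-area offset, system ⊂ region ⊂ continent
random intercepts, Wald statistics, and sensitivity refits on mountain
subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import substream
from .nbglmm import NBGlmmResult, fit_nb_glmm_arrays

__all__ = [
    "ModelSpec",
    "GlmmFit",
    "collinearity_screen",
    "standardize",
    "back_transform",
    "fit_nb_glmm",
    "taxon_models",
    "sensitivity_refits",
]

GEOMETRY_BASELINE = "diamond"
RANDOM_LEVELS = (("system", "system_id"), ("region", "region_id"), ("continent", "continent_id"))


@dataclass
class ModelSpec:
    """What to fit: response, predictors, offset and grouping columns."""

    response: str = "count"
    predictors: tuple = (
        "pop_density",
        "road_density",
        "dist_cities",
        "dist_ports",
        "bii",
        "gvocc_tmin",
        "roughness",
        "elev_range",
        "completeness",
    )
    geometry_column: str | None = "geometry"
    offset_area: str = "area_km2"
    taxon_scope: str = "all"
    standardize: bool = True
    min_rows_per_effect: int = 10
    min_groups_per_level: int = 5


@dataclass
class GlmmFit:
    """Tidy view of one fitted model."""

    coef: pd.DataFrame  # term, estimate, se, z, p
    theta: float
    sigma: dict
    loglik: float
    n_obs: int
    n_dropped: int
    converged: bool
    singular: bool
    scope: str
    scaler: dict = field(default_factory=dict)
    raw: NBGlmmResult | None = None


def collinearity_screen(
    predictors: pd.DataFrame, threshold: float = 0.7
) -> tuple[list, pd.DataFrame]:
    """Iteratively drop numeric predictors until no pair has |r| > threshold.

    At each step the predictor with the largest mean absolute correlation
    to all remaining others goes first (ties broken by column order).
    Returns (retained column names, full correlation matrix).
    """
    num = predictors.select_dtypes(include=[np.number])
    if len(num) < 2:
        raise ValueError("need at least 2 rows to screen collinearity")
    corr = num.corr()
    cols = list(num.columns)
    while True:
        sub = corr.loc[cols, cols].abs()
        np.fill_diagonal(sub.values, 0.0)
        if (sub.values > threshold).sum() == 0:
            break
        worst = sub.mean(axis=1)
        over = sub.max(axis=1) > threshold
        candidates = worst[over]
        drop = candidates.idxmax()  # first occurrence wins ties (column order)
        cols.remove(drop)
    return cols, corr


def standardize(predictors: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Scale numeric columns to mean 0, sample SD 1; return (scaled, scaler)."""
    out = predictors.copy()
    scaler = {}
    for col in predictors.select_dtypes(include=[np.number]).columns:
        x = predictors[col].to_numpy(dtype=float)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance predictor {col!r} cannot be standardized")
        out[col] = (x - mean) / sd
        scaler[col] = (mean, sd)
    return out, scaler


def back_transform(scaled: pd.DataFrame, scaler: dict) -> pd.DataFrame:
    """Invert :func:`standardize`."""
    out = scaled.copy()
    for col, (mean, sd) in scaler.items():
        out[col] = scaled[col] * sd + mean
    return out


def _build_design(spec: ModelSpec, data: pd.DataFrame):
    cols = [spec.response, spec.offset_area, *spec.predictors]
    cols += [c for _, c in RANDOM_LEVELS]
    if spec.geometry_column:
        cols.append(spec.geometry_column)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns {missing}")
    df = data[cols].replace([np.inf, -np.inf], np.nan)
    complete = df.dropna()
    n_dropped = len(df) - len(complete)

    pred = complete[list(spec.predictors)].astype(float)
    scaler = {}
    if spec.standardize:
        pred, scaler = standardize(pred)
    terms = ["(intercept)"]
    blocks = [np.ones((len(complete), 1))]
    blocks.append(pred.to_numpy())
    terms += list(spec.predictors)
    if spec.geometry_column:
        geom = complete[spec.geometry_column].astype(str)
        levels = [l for l in sorted(geom.unique()) if l != GEOMETRY_BASELINE]
        for lev in levels:
            blocks.append((geom == lev).to_numpy(float)[:, None])
            terms.append(f"geometry[{lev}]")
    X = np.hstack(blocks)
    y = complete[spec.response].to_numpy(dtype=float)
    offset = np.log(complete[spec.offset_area].to_numpy(dtype=float))
    groups = {
        name: complete[col].astype("category").cat.codes.to_numpy()
        for name, col in RANDOM_LEVELS
    }
    return y, X, offset, groups, terms, scaler, n_dropped, complete.index


def fit_nb_glmm(spec: ModelSpec, data: pd.DataFrame) -> GlmmFit:
    """Fit the NB2 mixed model per ``spec`` on a per-mountain table.

    Complete cases only (dropped rows are counted); every random level
    needs ≥ 5 groups; non-convergence and singular (boundary) variance
    fits are flagged, never silently returned.
    """
    y, X, offset, groups, terms, scaler, n_dropped, _ = _build_design(spec, data)
    if len(y) < spec.min_rows_per_effect * X.shape[1]:
        raise ValueError(
            f"too few rows ({len(y)}) for {X.shape[1]} fixed effects "
            f"(need >= {spec.min_rows_per_effect} rows per effect)"
        )
    for name, codes in groups.items():
        n_groups = len(np.unique(codes))
        if n_groups < spec.min_groups_per_level:
            raise ValueError(
                f"random level {name!r} has {n_groups} groups "
                f"(< {spec.min_groups_per_level})"
            )
    res = fit_nb_glmm_arrays(y, X, offset, groups)
    coef = pd.DataFrame(
        {
            "term": terms,
            "estimate": res.beta,
            "se": res.se,
            "z": res.zvalues,
            "p": res.pvalues,
        }
    )
    return GlmmFit(
        coef=coef,
        theta=res.theta,
        sigma=res.sigma,
        loglik=res.loglik,
        n_obs=res.n_obs,
        n_dropped=n_dropped,
        converged=res.converged,
        singular=res.singular,
        scope=spec.taxon_scope,
        scaler=scaler,
        raw=res,
    )


def taxon_models(
    spec: ModelSpec, data: pd.DataFrame, classes, response_pattern: str = "count_{}"
) -> dict:
    """Refit the model per taxon class on its occupied-mountain subset.

    The response for class ``c`` is the ``response_pattern`` column; only
    mountains with ≥ 1 alien species of the class enter, and
    standardization is recomputed within each subset.  Subsets too small
    for the fixed-effect count raise (refusal, not an empty fit).
    """
    out = {}
    for cls in classes:
        col = response_pattern.format(cls)
        if col not in data.columns:
            raise ValueError(f"no response column {col!r} for class {cls!r}")
        sub = data[data[col] > 0]
        if len(sub) == 0:
            raise ValueError(f"class {cls!r} absent from data")
        cls_spec = ModelSpec(
            response=col,
            predictors=spec.predictors,
            geometry_column=spec.geometry_column,
            offset_area=spec.offset_area,
            taxon_scope=cls,
            standardize=spec.standardize,
            min_rows_per_effect=spec.min_rows_per_effect,
            min_groups_per_level=spec.min_groups_per_level,
        )
        out[cls] = fit_nb_glmm(cls_spec, sub)
    return out


def sensitivity_refits(
    spec: ModelSpec,
    data: pd.DataFrame,
    rules=("random80x10", "drop_continent"),
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Refit on mountain subsets and summarize coefficient stability.

    Built-in rules: ``random<P>x<K>`` draws K random P% subsets;
    ``drop_continent`` leaves each continent out in turn; ``full``
    repeats the full data.  A custom rule may be a ``(name, [index...])``
    tuple.  Returns one row per coefficient with the fraction of
    successful subsets preserving its full-fit sign, the fraction
    significant at ``alpha``, and the subset failure count.
    """
    full = fit_nb_glmm(spec, data)
    ref_sign = np.sign(full.coef.set_index("term")["estimate"])
    rng = substream(seed, "sensitivity")
    subsets = []
    for rule in rules:
        if isinstance(rule, tuple):
            subsets.append(rule)
        elif rule == "full":
            subsets.append(("full", data.index))
        elif rule.startswith("random"):
            pct, k = rule[len("random") :].split("x")
            frac, k = int(pct) / 100.0, int(k)
            for i in range(k):
                take = rng.choice(len(data), size=int(round(frac * len(data))), replace=False)
                subsets.append((f"{rule}#{i + 1}", data.index[np.sort(take)]))
        elif rule == "drop_continent":
            for cont in sorted(data["continent_id"].unique()):
                subsets.append((f"drop:{cont}", data.index[data["continent_id"] != cont]))
        else:
            raise ValueError(f"unknown sensitivity rule {rule!r}")
    if len(subsets) < 2:
        raise ValueError("need at least 2 subset rules")

    records = {t: {"same_sign": 0, "significant": 0, "n_ok": 0} for t in ref_sign.index}
    n_failed = 0
    failures = []
    for name, idx in subsets:
        try:
            fit = fit_nb_glmm(spec, data.loc[idx])
        except Exception as exc:  # refusal or numerical failure — recorded
            n_failed += 1
            failures.append({"subset": name, "error": str(exc)})
            continue
        sub = fit.coef.set_index("term")
        for t in ref_sign.index:
            if t not in sub.index:
                continue
            rec = records[t]
            rec["n_ok"] += 1
            if np.sign(sub.loc[t, "estimate"]) == ref_sign[t]:
                rec["same_sign"] += 1
            if sub.loc[t, "p"] < alpha:
                rec["significant"] += 1
    rows = []
    for t, rec in records.items():
        n = max(rec["n_ok"], 1)
        rows.append(
            {
                "term": t,
                "sign_stability": rec["same_sign"] / n,
                "significance_fraction": rec["significant"] / n,
                "n_subsets_ok": rec["n_ok"],
                "n_subsets_failed": n_failed,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["failures"] = failures
    return out
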