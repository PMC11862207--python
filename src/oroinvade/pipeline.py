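"""End-to-end orchestration: configuration, input validation, staged runs.

A run is driven by one YAML config (thresholds default to the protocol
constants: dip 0.01, dip-test p 0.05, |skew| 0.5, |r| 0.7, 999 null
draws).  All randomness derives from the root seed through named
substreams; stage outputs are plain CSV/JSON so reruns are byte-stable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import substream
from .geoio import read_geojson
from .ingest_filter import assign_mountain, filter_native_overlap, richness_table, validate_disjoint
from .invasion_glmm import ModelSpec, collinearity_screen, fit_nb_glmm, taxon_models
from .mountain_metrics import classify_geometry, extract_predictors, gvocc, terrain_roughness
from .protected_areas import filter_pas, pa_overlap, pa_summaries
from .raster import Raster, zonal_mask
from .realm_flows import assign_realms, export_chord, flow_matrix, null_flow_test
from .synthworld import (
    TAXON_CLASSES,
    Mountain,
    ProtectedArea,
    SpeciesRange,
    WorldConfig,
    generate_world,
    write_world,
)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_layers"]

CONFIG_SCHEMA_VERSION = "1"

DEFAULT_THRESHOLDS = {
    "dip": 0.01,
    "p_dip": 0.05,
    "skew": 0.5,
    "max_abs_r": 0.7,
    "n_draws": 999,
}


@dataclass
class RunConfig:
    out_dir: str = "runs/out"
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "synth": True,
            "filter": True,
            "metrics": True,
            "flows": True,
            "pa": True,
            "fit": True,
        }
    )
    inputs: dict = field(default_factory=dict)  # layer name -> path (when synth off)
    thresholds: dict = field(default_factory=dict)
    world: dict = field(default_factory=dict)  # WorldConfig overrides for synth
    fit_options: dict = field(default_factory=dict)  # ModelSpec overrides (e.g. min_rows_per_effect)

    def __post_init__(self):
        self.thresholds = {**DEFAULT_THRESHOLDS, **self.thresholds}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {"out_dir", "seed", "stages", "inputs", "thresholds", "world", "fit_options"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        cfg.out_dir = raw.get("out_dir", cfg.out_dir)
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.stages.update(raw.get("stages", {}))
        cfg.inputs.update(raw.get("inputs", {}))
        cfg.thresholds.update(raw.get("thresholds", {}))
        cfg.world.update(raw.get("world", {}))
        cfg.fit_options.update(raw.get("fit_options", {}))
        return cfg


# ------------------------------------------------------------------------ loaders


def load_layers(inputs: dict) -> dict:
    """Load file-based layers into the in-memory model objects."""
    layers = {}
    if "mountains" in inputs:
        feats = read_geojson(inputs["mountains"])
        layers["mountains"] = [
            Mountain(
                mountain_id=f["mountain_id"],
                polygon=f["geometry"],
                system_id=f["system_id"],
                region_id=f["region_id"],
                continent_id=f["continent_id"],
                area_km2=float(f["area_km2"]),
                elev_min=float(f.get("elev_min", float("nan"))),
                elev_max=float(f.get("elev_max", float("nan"))),
            )
            for f in feats
        ]
    if "ranges" in inputs:
        feats = read_geojson(inputs["ranges"])
        layers["ranges"] = [
            SpeciesRange(
                species_id=f["species_id"],
                taxon_class=f["taxon_class"],
                native_polygons=f["geometry"],
            )
            for f in feats
        ]
    if "realms" in inputs:
        layers["realms"] = read_geojson(inputs["realms"])
    if "pas" in inputs:
        feats = read_geojson(inputs["pas"])
        layers["pas"] = [
            ProtectedArea(
                pa_id=f["pa_id"],
                polygon=f["geometry"],
                status=f.get("status", ""),
                iucn_category=f.get("iucn_cat") or f.get("iucn_category"),
            )
            for f in feats
        ]
    if "records" in inputs:
        occ = pd.read_csv(inputs["records"])
        occ = occ.rename(
            columns={"decimalLongitude": "lon", "decimalLatitude": "lat"}
        )
        layers["records"] = occ
    for name in ("dem", "pop_density", "road_density", "bii", "completeness"):
        if name in inputs:
            layers[name] = Raster.read_ascii(inputs[name])
    if "climate" in inputs:
        import xarray as xr

        layers["climate"] = xr.open_dataarray(inputs["climate"], engine="scipy")
    for name in ("cities", "ports"):
        if name in inputs:
            feats = read_geojson(inputs[name])
            layers[name] = pd.DataFrame(
                [
                    {
                        **{k: v for k, v in f.items() if k != "geometry"},
                        "lon": f["geometry"].x,
                        "lat": f["geometry"].y,
                    }
                    for f in feats
                ]
            )
    return layers


# --------------------------------------------------------------------- validation


REQUIRED_OCC_COLUMNS = {"record_id", "species_id", "taxon_class", "lon", "lat"}


def validate_inputs(paths: dict) -> dict:
    """Schema/geometry checks per layer; fatal errors vs non-fatal warnings."""
    report = {"fatal": [], "warnings": []}
    try:
        layers = load_layers(paths)
    except (OSError, ValueError, KeyError) as exc:
        report["fatal"].append(f"unreadable input: {exc}")
        return report
    if "records" in layers:
        occ = layers["records"]
        missing = REQUIRED_OCC_COLUMNS - set(occ.columns)
        if missing:
            report["fatal"].append(f"occurrence CSV missing columns {sorted(missing)}")
        else:
            bad_lon = (~occ["lon"].between(-180, 180)).sum()
            bad_lat = (~occ["lat"].between(-90, 90)).sum()
            if bad_lon or bad_lat:
                report["fatal"].append(
                    f"{bad_lon + bad_lat} records with out-of-range coordinates"
                )
            unknown_cls = set(occ["taxon_class"].unique()) - set(TAXON_CLASSES)
            if unknown_cls:
                report["fatal"].append(f"unknown taxon classes {sorted(unknown_cls)}")
    if "mountains" in layers:
        try:
            validate_disjoint(layers["mountains"])
        except ValueError as exc:
            report["fatal"].append(str(exc))
    if "pas" in layers:
        from .protected_areas import _VALID_STATUS

        for pa in layers["pas"]:
            if (pa.status or "").strip().lower() not in _VALID_STATUS | {
                "proposed",
                "adopted",
                "not reported",
            }:
                report["warnings"].append(
                    f"PA {pa.pa_id}: unknown status {pa.status!r} (row excluded downstream)"
                )
    return report


# --------------------------------------------------------------------------- run


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> int:
    df.to_csv(path, index=kw.pop("index", False), **kw)
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in dependency order and write a manifest.

    Returns the manifest dict.  Any stage failure raises after the
    partial outputs and a partial manifest have been written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage, **fields):
        log_fh.write(json.dumps({"stage": stage, **fields}, sort_keys=True) + "\n")
        log_fh.flush()

    manifest = {
        "version": __version__,
        "config_schema_version": CONFIG_SCHEMA_VERSION,
        "seed": config.seed,
        "thresholds": dict(config.thresholds),
        "stages": {k: bool(v) for k, v in config.stages.items()},
        "stage_outputs": {},
    }
    thr = config.thresholds
    stages = config.stages
    state: dict = {}

    try:
        if stages.get("synth"):
            wc = WorldConfig(**{**{"seed": config.seed}, **config.world})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                world = generate_world(wc)
            synth_dir = out / "synth"
            write_world(world, synth_dir)
            state.update(
                mountains=world.mountains,
                ranges=world.species,
                realms=world.realms,
                pas=world.pas,
                records=world.occurrences,
                dem=world.dem,
                climate=world.climate_series,
                cities=world.cities,
                ports=world.ports,
                **{k: v for k, v in world.predictor_rasters.items()},
            )
            state["world"] = world
            log("synth", n_records=len(world.occurrences), n_mountains=len(world.mountains))
            manifest["stage_outputs"]["synth"] = str(synth_dir)
        elif config.inputs:
            state.update(load_layers(config.inputs))

        if stages.get("filter"):
            for need in ("records", "mountains", "ranges"):
                if need not in state:
                    raise RuntimeError(f"filter stage requires {need!r} (enable synth or provide inputs)")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                annotated = assign_mountain(state["records"], state["mountains"])
                kept, discarded = filter_native_overlap(annotated, state["ranges"])
            state["kept"] = kept
            rich = richness_table(kept, state["mountains"])
            state["richness"] = rich
            n1 = _write_csv(kept, out / "records_kept.csv")
            n2 = _write_csv(discarded, out / "records_discarded.csv")
            n3 = _write_csv(rich, out / "richness.csv")
            log("filter", kept=n1, discarded=n2, richness_rows=n3)
            manifest["stage_outputs"]["filter"] = ["records_kept.csv", "records_discarded.csv", "richness.csv"]

        if stages.get("metrics"):
            for need in ("dem", "mountains", "climate"):
                if need not in state:
                    raise RuntimeError(f"metrics stage requires {need!r}")
            rough = terrain_roughness(state["dem"])
            velocity = gvocc(state["climate"])
            geometry = {}
            for m in state["mountains"]:
                sample = state["dem"].data[zonal_mask(state["dem"], m.polygon)]
                try:
                    geometry[m.mountain_id] = classify_geometry(
                        sample,
                        m.mountain_id,
                        dip_threshold=thr["dip"],
                        p_threshold=thr["p_dip"],
                        skew_threshold=thr["skew"],
                    )
                except ValueError:
                    geometry[m.mountain_id] = None
            rasters = {
                k: state[k]
                for k in ("pop_density", "road_density", "bii", "completeness")
                if k in state
            }
            predictors = extract_predictors(
                state["mountains"],
                rasters,
                state.get("cities", pd.DataFrame(columns=["lon", "lat"])),
                state.get("ports", pd.DataFrame(columns=["lon", "lat"])),
                velocity=velocity,
                geometry_classes=geometry,
                roughness=rough,
            )
            state["predictors"] = predictors
            _write_csv(predictors, out / "predictors.csv", index=True)
            meta = {
                "zonal_rule": "cell center in polygon",
                "distance": "great-circle km, nearest boundary point",
                "gvocc": "annual means OLS trend over climatology gradient",
                "skewness": "moment coefficient (biased)",
                "dip_pvalue": "Monte-Carlo vs uniform null",
            }
            (out / "predictors_meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
            log("metrics", n_mountains=len(predictors))
            manifest["stage_outputs"]["metrics"] = ["predictors.csv", "predictors_meta.json"]

        if stages.get("flows"):
            for need in ("kept", "ranges", "realms"):
                if need not in state:
                    raise RuntimeError(f"flows stage requires {need!r} (run filter first)")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kept_r = assign_realms(state["ranges"], state["realms"], state["kept"])
            state["kept"] = kept_r
            fm = flow_matrix(kept_r, state["ranges"], "all")
            fm.counts.to_csv(out / "flow_matrix.csv")
            _write_csv(export_chord(fm), out / "flow_chord.csv")
            pool = pd.DataFrame(
                {
                    "species_id": [r.species_id for r in state["ranges"]],
                    "native_realms": [r.native_realms for r in state["ranges"]],
                }
            )
            pool = pool[pool["native_realms"].map(len) > 0]
            null = null_flow_test(
                fm, pool, n_draws=int(thr["n_draws"]), seed=int(config.seed)
            )
            null["scope"] = "all"
            _write_csv(null, out / "flow_null_test.csv")
            state["flow"] = fm
            log("flows", cells=int((fm.counts.values > 0).sum()))
            manifest["stage_outputs"]["flows"] = [
                "flow_matrix.csv",
                "flow_chord.csv",
                "flow_null_test.csv",
            ]

        if stages.get("pa"):
            for need in ("kept", "pas", "mountains"):
                if need not in state:
                    raise RuntimeError(f"pa stage requires {need!r} (run filter first)")
            pas_kept, rejected = filter_pas(state["pas"])
            annotated = pa_overlap(state["kept"].dropna(subset=["mountain_id"]), pas_kept)
            summaries = pa_summaries(
                annotated, pas_kept, state["mountains"], state.get("realms")
            )
            _write_csv(rejected, out / "pa_rejected.csv")
            _write_csv(summaries["per_category"], out / "pa_per_category.csv")
            if summaries["per_realm_category"] is not None:
                _write_csv(summaries["per_realm_category"], out / "pa_per_realm_category.csv")
            meta = {"overlap_rule": "record counts once per containing PA; species de-duplicated within category"}
            (out / "pa_meta.json").write_text(json.dumps(meta, sort_keys=True))
            log("pa", n_pas_kept=len(pas_kept), n_annotations=len(annotated))
            manifest["stage_outputs"]["pa"] = ["pa_per_category.csv", "pa_per_realm_category.csv", "pa_rejected.csv"]

        if stages.get("fit"):
            for need in ("richness", "predictors"):
                if need not in state:
                    raise RuntimeError(f"fit stage requires {need!r} (run filter+metrics first)")
            rich = state["richness"]
            wide = (
                rich[rich["taxon_class"] == "all"]
                .set_index("mountain_id")["n_species"]
                .rename("count")
                .to_frame()
            )
            for cls in TAXON_CLASSES:
                sub = rich[rich["taxon_class"] == cls].set_index("mountain_id")["n_species"]
                wide[f"count_{cls}"] = sub
            data = state["predictors"].join(wide, how="inner")
            data["count"] = data["count"].fillna(0).astype(int)
            data["geometry"] = data["geometry"].astype(object)

            numeric = [
                p
                for p in ModelSpec().predictors
                if p in data.columns and data[p].notna().any()
            ]
            retained, corr = collinearity_screen(
                data[numeric].dropna(), threshold=float(thr["max_abs_r"])
            )
            corr.to_csv(out / "predictor_correlations.csv")
            spec = ModelSpec(predictors=tuple(retained), **config.fit_options)
            fit = fit_nb_glmm(spec, data)
            fit.coef.assign(scope="all").to_csv(out / "glmm_coefficients.csv", index=False)
            ranef = {"sigma": fit.sigma, "theta": fit.theta, "loglik": fit.loglik,
                     "converged": fit.converged, "singular": fit.singular,
                     "n_obs": fit.n_obs, "n_dropped": fit.n_dropped,
                     "statistic_note": "Wald z statistics reported"}
            (out / "glmm_random_effects.json").write_text(json.dumps(ranef, sort_keys=True, indent=1))
            log("fit", n_obs=fit.n_obs, converged=fit.converged)
            manifest["stage_outputs"]["fit"] = [
                "glmm_coefficients.csv",
                "glmm_random_effects.json",
                "predictor_correlations.csv",
            ]
    except Exception as exc:
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        log_fh.close()
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    log_fh.close()
    return manifest
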