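"""End-to-end orchestration: data preparation, niche comparisons, ensemble
modelling and projection/risk, driven by one YAML config and one master seed.

Three analysis modes mirror the study designs the package supports:

* ``synthetic-demo`` — generates a virtual climate, a virtual species with a
  known native/invasive niche shift, and synthetic country polygons, then
  runs every stage; the whole run is reproducible bit-for-bit from the seed.
* ``combined`` — real inputs, all occurrences pooled into one taxon.
* ``by-species`` — real inputs, comparisons listed per (taxon, region) pair.

Every stage writes its products under the run directory together with a
manifest (package version, config hash, stage seeds, input checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble import (
    build_ensemble,
    fit_all_members,
    make_training_set,
    sample_pseudo_absences,
    split_train_eval,
)
from .niche import compare_niches
from .occurrences import (
    assign_status,
    background_env,
    extract_env,
    read_geojson_polygons,
    read_occurrences,
    select_variables,
    thin_to_grid,
)
from .projection import binarize, change_map, country_risk, project
from .raster import ClimateStack
from .synthetic import (
    ShiftScenario,
    VirtualNicheSpec,
    default_climate_spec,
    generate_climate_stack,
    make_shift_scenario,
)

log = logging.getLogger("nichesdm")

__all__ = ["RunConfig", "run"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


@dataclass
class RunConfig:
    """Run settings; every stochastic stage derives its seed from ``seed``."""

    mode: str = "synthetic-demo"  # synthetic-demo | combined | by-species
    seed: int = 0
    # real-data inputs (ignored in synthetic-demo)
    occurrences: str | None = None
    climate_current: str | None = None
    climate_scenarios: dict[str, str] = field(default_factory=dict)
    native_range: str | None = None
    regions: str | None = None
    countries: str | None = None
    comparisons: list[dict] = field(default_factory=list)
    # variable selection
    preferred_variables: list[str] = field(
        default_factory=lambda: ["bio4", "bio5", "bio6", "bio12", "bio15"]
    )
    correlation_threshold: float = 0.8
    # niche settings
    niche_R: int = 100
    intersection_quantile: float = 0.0
    n_permutations: int = 0
    # SDM settings
    n_pseudo_absences: int = 10000
    exclusion_radius_km: float | None = None
    train_fraction: float = 0.8
    auc_cutoff: float = 0.95
    # synthetic-demo sizes
    demo_extent: tuple = (-10.0, 35.0, 10.0, 55.0)
    demo_n_native: int = 800
    demo_n_invasive: int = 800

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("synthetic-demo", "combined", "by-species"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode != "synthetic-demo":
            missing = [
                name
                for name, p in [
                    ("occurrences", self.occurrences),
                    ("climate_current", self.climate_current),
                ]
                if not p or not Path(p).exists()
            ]
            for name, p in [("native_range", self.native_range),
                            ("countries", self.countries)]:
                if p and not Path(p).exists():
                    missing.append(name)
            for tag, p in self.climate_scenarios.items():
                if not Path(p).exists():
                    missing.append(f"climate_scenarios[{tag}]")
            if missing:
                raise ConfigError(f"missing input files: {missing}")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["demo_extent"] = list(self.demo_extent)
        return d


def _stage_seeds(master: int) -> dict[str, int]:
    """Fan the master seed out to named per-stage seeds (all < 2^31)."""
    rng = np.random.default_rng(master)
    names = ["synthesis", "pseudo_absences", "split", "members", "permutations"]
    return {n: int(s) for n, s in zip(names, rng.integers(0, 2**31 - 1, len(names)))}


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _subset(occ: pd.DataFrame, filt: dict | None) -> pd.DataFrame:
    if not filt:
        return occ
    mask = np.ones(len(occ), dtype=bool)
    for col in ("species", "status", "region"):
        if col in filt:
            mask &= (occ[col] == filt[col]).to_numpy()
    return occ.loc[mask]


def _demo_inputs(cfg: RunConfig, seeds: dict):
    """Virtual climate, shifted virtual species and synthetic countries."""
    import shapely.geometry as sgeom

    spec = default_climate_spec(extent=cfg.demo_extent, seed=seeds["synthesis"])
    climate = generate_climate_stack(spec)
    layers = ("bio4", "bio5", "bio12")
    native = VirtualNicheSpec(layers, optimum=(600.0, 22.0, 1500.0),
                              breadth=(90.0, 2.5, 280.0))
    invasive = VirtualNicheSpec(layers, optimum=(640.0, 24.5, 1350.0),
                                breadth=(100.0, 2.8, 300.0))
    scenario = ShiftScenario(
        native_niche=native,
        invasive_niche=invasive,
        n_native=cfg.demo_n_native,
        n_invasive=cfg.demo_n_invasive,
        seed=seeds["synthesis"],
    )
    occ_nat, occ_inv, truth = make_shift_scenario(scenario, climate)
    occ = pd.concat([occ_nat, occ_inv], ignore_index=True)

    # a mildly warmer/drier future of the same virtual world
    future_layers = dict(climate.layers)
    future_layers["bio5"] = climate.layers["bio5"] + 3.0
    future_layers["bio6"] = climate.layers["bio6"] + 4.0
    future_layers["bio12"] = climate.layers["bio12"] * 0.92
    future = ClimateStack(
        layers=future_layers,
        transform=climate.transform,
        nodata_mask=climate.nodata_mask.copy(),
    )

    west, south, east, north = cfg.demo_extent
    mid_lon, mid_lat = (west + east) / 2, (south + north) / 2
    countries = [
        ("northwest", sgeom.box(west, mid_lat, mid_lon, north)),
        ("northeast", sgeom.box(mid_lon, mid_lat, east, north)),
        ("southwest", sgeom.box(west, south, mid_lon, mid_lat)),
        ("southeast", sgeom.box(mid_lon, south, east, mid_lat)),
    ]
    return climate, {"future": future}, occ, countries, truth


def run(cfg: RunConfig, outdir, stages=("niche", "sdm", "risk")) -> Path:
    """Execute the configured analysis; returns the run directory.

    Any stage failure aborts with a :class:`StageError` naming the stage; a
    ``partial_results.json`` index lists what had already been written.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    written: list[str] = []
    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seeds": seeds,
        "input_checksums": {},
    }

    def emit(name: str, payload) -> None:
        path = outdir / name
        if isinstance(payload, pd.DataFrame):
            payload.to_csv(path, index=False)
        else:
            path.write_text(json.dumps(payload, indent=2, default=float))
        written.append(name)

    def fail(stage: str, exc: Exception):
        emit("partial_results.json", {"failed_stage": stage, "written": written})
        raise StageError(stage, exc)

    # ---------------- data preparation ----------------
    try:
        if cfg.mode == "synthetic-demo":
            climate, future_stacks, occ, countries, truth = _demo_inputs(cfg, seeds)
            cleaning = {"mode": "synthetic-demo", "n_records": int(len(occ))}
        else:
            occ, log_ = read_occurrences(cfg.occurrences)
            cleaning = log_.__dict__
            manifest["input_checksums"][cfg.occurrences] = _checksum(cfg.occurrences)
            climate = ClimateStack.from_geotiff(cfg.climate_current)
            manifest["input_checksums"][cfg.climate_current] = _checksum(
                cfg.climate_current
            )
            future_stacks = {}
            for tag, p in cfg.climate_scenarios.items():
                future_stacks[tag] = ClimateStack.from_geotiff(p)
                manifest["input_checksums"][p] = _checksum(p)
            if cfg.native_range:
                polys = read_geojson_polygons(cfg.native_range)
                regions = (
                    read_geojson_polygons(cfg.regions) if cfg.regions else None
                )
                occ = assign_status(occ, polys, regions)
            countries = (
                read_geojson_polygons(cfg.countries) if cfg.countries else []
            )
        occ = thin_to_grid(occ, climate)
        cleaning["n_after_thinning"] = int(len(occ))
        selection = select_variables(
            climate, cfg.correlation_threshold, tuple(cfg.preferred_variables)
        )
        chosen = selection.chosen
        log.info("thinned to %d records; variables: %s", len(occ), chosen)
        emit("cleaning_log.json", cleaning)
        emit(
            "variable_selection.json",
            {
                "chosen": chosen,
                "clusters": selection.clusters,
                "threshold": selection.threshold,
            },
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("data_prep", exc)

    # ---------------- niche comparisons ----------------
    if "niche" in stages:
        try:
            comparisons = cfg.comparisons or [
                {
                    "name": "native_vs_invasive",
                    "first": {"status": "native"},
                    "second": {"status": "invasive"},
                }
            ]
            bg = background_env(climate, chosen)
            reports = {}
            for comp in comparisons:
                occ1 = _subset(occ, comp.get("first"))
                occ2 = _subset(occ, comp.get("second"))
                env1 = extract_env(occ1, climate, chosen, "presence")
                env2 = extract_env(occ2, climate, chosen, "presence")
                pca, g1, g2, result = compare_niches(
                    env1,
                    env2,
                    bg,
                    bg,
                    R=cfg.niche_R,
                    intersection_quantile=cfg.intersection_quantile,
                    n_perm=cfg.n_permutations,
                    seed=seeds["permutations"],
                )
                name = comp.get("name", "comparison")
                reports[name] = {
                    **result.to_dict(),
                    "n_first": int(len(occ1)),
                    "n_second": int(len(occ2)),
                    "pca_explained_2d": pca.explained_2d,
                }
                from .viz import plot_niche_comparison

                plot_niche_comparison(g1, g2, outdir / f"niche_{name}.png")
                written.append(f"niche_{name}.png")
            if cfg.mode == "synthetic-demo":
                reports["native_vs_invasive"]["oracle"] = {
                    "d": truth.d,
                    "expansion": truth.expansion,
                    "stability": truth.stability,
                    "unfilling": truth.unfilling,
                }
            emit("niche_reports.json", reports)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail("niche_dynamics", exc)

    # ---------------- ensemble SDM + projection ----------------
    ens = None
    if "sdm" in stages:
        try:
            pa = sample_pseudo_absences(
                occ,
                climate,
                n=cfg.n_pseudo_absences,
                exclusion_radius_km=cfg.exclusion_radius_km,
                seed=seeds["pseudo_absences"],
            )
            ts = make_training_set(
                extract_env(occ, climate, chosen, "presence"),
                extract_env(pa, climate, chosen, "absence"),
            )
            train, evaluation = split_train_eval(
                ts, cfg.train_fraction, seed=seeds["split"]
            )
            members = fit_all_members(train, evaluation, seed=seeds["members"])
            ens = build_ensemble(members, cutoff=cfg.auc_cutoff)
            ens.evaluate(evaluation)
            emit("ensemble_manifest.json", ens.manifest())

            current_map = project(ens, climate, "current", chosen)
            current_map.to_geotiff(outdir / "suitability_current.tif")
            written.append("suitability_current.tif")
            current_bin = binarize(current_map, ens.threshold)
            change_summary = {}
            for tag, stack in future_stacks.items():
                fmap = project(ens, stack, tag, chosen)
                fmap.to_geotiff(outdir / f"suitability_{tag}.tif")
                written.append(f"suitability_{tag}.tif")
                cmap_ = change_map(current_bin, binarize(fmap, ens.threshold))
                change_summary[tag] = cmap_.counts
            emit("range_change.json", change_summary)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail("ensemble_sdm", exc)

    # ---------------- country risk ----------------
    if "risk" in stages and ens is not None and countries:
        try:
            tables = [country_risk(project(ens, climate, "current", chosen), countries)]
            for tag, stack in future_stacks.items():
                tables.append(country_risk(project(ens, stack, tag, chosen), countries))
            emit("risk_table.csv", pd.concat(tables, ignore_index=True))
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail("projection_risk", exc)

    manifest["written"] = written
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=float)
    )
    return outdir
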