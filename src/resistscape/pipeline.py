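"""Pipeline orchestration: stages, config validation, artifacts, manifests.

Each stage reads its inputs from the configured paths (or from the
artifacts of the producing stage under the same output directory), writes
its artifacts under ``<out>/<stage>/``, and records a manifest with the
config hash, the seeds used and package versions. Reruns with an
identical config and seed are bit-identical for the deterministic stages.

Stage order: simulate -> fst -> prep -> optimize -> select -> map ->
project; ``all`` chains them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity_mapping import (
    NodeGrid,
    PassageMap,
    corridor_mask,
    cumulative_passage_map,
    difference_map,
    place_node_grid,
)
from .effective_distance import RSPConfig, build_transition_graph, commute_distance_matrix
from .genetics import pairwise_fst, read_genotypes
from .grids import RasterGrid
from .mlpe import build_design, fit_mlpe
from .model_selection import BootstrapCandidate, bootstrap_ranking, enumerate_candidates, rank_models
from .optimizer import (
    GAConfig,
    SurfaceModel,
    ibd_surface,
    replicate_runs,
    sites_to_nodes,
    surface_from_model,
)
from .raster_prep import mcp_buffer_extent, read_raster, vif_filter, write_raster
from .resistance_transforms import average_surfaces
from .synthetic_landscape import SyntheticConfig, write_synthetic_dataset

log = logging.getLogger("resistscape")

STAGES = ("simulate", "fst", "prep", "optimize", "select", "map", "project", "all")

_DEFAULTS: dict = {
    "seed": 0,
    "synthetic": {},
    "paths": {},
    "vif_threshold": 2.5,
    "ga": {},                       # GAConfig overrides; n_replicate_runs=10
    "rsp": {"theta": 1e-6},
    "bootstrap": {"frac": 0.75, "n_boot": 1000},
    "corridor_keep_fraction": 0.5,
    "map": {"n_nodes": 400, "mcp_buffer_m": 75_000.0, "node_buffer_m": 25_000.0},
    "max_subset_size": 2,
    "future": {"offset": {"precipitation": 15.0}, "covariates": {}},
}


@dataclass
class PipelineConfig:
    raw: dict
    out_dir: Path
    seed: int

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def config_hash(self) -> str:
        doc = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def validate_config(doc: dict, out_dir, seed: int | None = None) -> PipelineConfig:
    """Merge with defaults and validate before any computation."""
    if not isinstance(doc, dict):
        raise ValueError("config must be a JSON object")
    unknown = set(doc) - set(_DEFAULTS) - {"out_dir"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {}
    for key, default in _DEFAULTS.items():
        v = doc.get(key, default)
        if isinstance(default, dict):
            if not isinstance(v, dict):
                raise ValueError(f"config key {key!r} must be an object")
            v = {**default, **v}
        merged[key] = v
    if seed is not None:
        merged["seed"] = seed
    if not isinstance(merged["seed"], int):
        raise ValueError("seed must be an integer")
    if not (0 < merged["corridor_keep_fraction"] <= 1):
        raise ValueError("corridor_keep_fraction must lie in (0, 1]")
    if not (0 < merged["bootstrap"]["frac"] <= 1):
        raise ValueError("bootstrap frac must lie in (0, 1]")
    # referenced input paths must exist before any stage runs
    for key, p in merged["paths"].items():
        if key == "covariates":
            for name, cp in p.items():
                if not Path(cp).exists():
                    raise ValueError(f"covariate path for {name!r} missing: {cp}")
        elif not Path(p).exists():
            raise ValueError(f"configured path {key!r} does not exist: {p}")
    # validate nested configs eagerly so schema errors precede computation
    SyntheticConfig(**merged["synthetic"], seed=merged["seed"])
    GAConfig(**merged["ga"], seed=merged["seed"])
    RSPConfig(theta=merged["rsp"]["theta"])
    return PipelineConfig(raw=merged, out_dir=Path(out_dir), seed=merged["seed"])


def _stage_seed(cfg: PipelineConfig, *streams: int) -> int:
    return int(np.random.SeedSequence([cfg.seed, *streams]).generate_state(1)[0]
               % (2**31 - 1))


def _write_manifest(cfg: PipelineConfig, stage: str, artifacts: list[str]) -> None:
    sdir = cfg.out_dir / stage
    sdir.mkdir(parents=True, exist_ok=True)
    doc = {
        "stage": stage,
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "versions": {
            "resistscape": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": sorted(artifacts),
    }
    with open(sdir / "manifest.json", "w") as fh:
        json.dump(doc, fh, indent=2)


# ---------------------------------------------------------------- inputs


def _load_sites(cfg: PipelineConfig) -> pd.DataFrame:
    p = cfg["paths"].get("sites", cfg.out_dir / "simulate" / "sites.csv")
    if not Path(p).exists():
        raise FileNotFoundError(
            f"sites table not found at {p}; run the 'simulate' stage or set "
            "paths.sites"
        )
    return pd.read_csv(p)

def _load_covariates(cfg: PipelineConfig, stage_dir: str = "prep") -> dict[str, RasterGrid]:
    prep = cfg.out_dir / stage_dir
    if cfg["paths"].get("covariates") and stage_dir == "simulate":
        return {
            name: read_raster(p, name=name)
            for name, p in cfg["paths"]["covariates"].items()
        }
    files = sorted(prep.glob("covariate_*.asc"))
    if not files:
        raise FileNotFoundError(
            f"no covariates under {prep}; run the producing stage first"
        )
    out = {}
    for f in files:
        name = f.stem.removeprefix("covariate_")
        out[name] = read_raster(f, name=name)
    return out


def _load_fst(cfg: PipelineConfig) -> pd.DataFrame:
    p = cfg.out_dir / "fst" / "fst.csv"
    if not p.exists():
        raise FileNotFoundError(f"{p} not found; run the 'fst' stage first")
    return pd.read_csv(p, index_col=0)


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig) -> list[str]:
    sc = SyntheticConfig(**cfg["synthetic"], seed=cfg.seed)
    manifest = write_synthetic_dataset(sc, cfg.out_dir / "simulate")
    arts = list(manifest["covariates"].values()) + [
        manifest["sites"], manifest["genotypes"], manifest["truth"],
    ]
    _write_manifest(cfg, "simulate", arts)
    log.info("simulate: wrote %d covariates, %s sites", len(manifest["covariates"]),
             SyntheticConfig(**cfg["synthetic"], seed=cfg.seed).n_sites)
    return arts


def stage_fst(cfg: PipelineConfig) -> list[str]:
    gpath = cfg["paths"].get("genotypes", cfg.out_dir / "simulate" / "genotypes.csv")
    if not Path(gpath).exists():
        raise FileNotFoundError(
            f"genotypes not found at {gpath}; run 'simulate' or set paths.genotypes"
        )
    dialect = cfg["paths"].get("genotype_dialect", "genalex-simplified")
    g = read_genotypes(gpath, dialect=dialect)
    fst, meta = pairwise_fst(g)
    sdir = cfg.out_dir / "fst"
    sdir.mkdir(parents=True, exist_ok=True)
    fst.to_csv(sdir / "fst.csv")
    with open(sdir / "fst_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    _write_manifest(cfg, "fst", [str(sdir / "fst.csv"), str(sdir / "fst_meta.json")])
    log.info("fst: %d populations, %d negative pairwise estimates",
             len(fst), meta["n_negative"])
    return [str(sdir / "fst.csv")]


def stage_prep(cfg: PipelineConfig) -> list[str]:
    covs = _load_covariates(cfg, stage_dir="simulate")
    from .raster_prep import merge_host_defoliation

    if "host_cover" in covs and "defoliation" in covs:
        covs["host_cover_net"] = merge_host_defoliation(
            covs.pop("host_cover"), covs.pop("defoliation")
        )
    stack = list(covs.values())
    if len(stack) >= 2:
        diag = vif_filter(stack, threshold=cfg["vif_threshold"])
        kept = diag.kept
        diag_doc = diag.to_dict()
    else:
        kept = [stack[0].name]
        diag_doc = {"threshold": cfg["vif_threshold"], "kept": kept,
                    "dropped": [], "vif": {}}
    sdir = cfg.out_dir / "prep"
    sdir.mkdir(parents=True, exist_ok=True)
    arts = []
    for name in kept:
        p = sdir / f"covariate_{name}.asc"
        write_raster(covs[name], p)
        arts.append(str(p))
    with open(sdir / "diagnostics.json", "w") as fh:
        json.dump(diag_doc, fh, indent=2)
    arts.append(str(sdir / "diagnostics.json"))
    _write_manifest(cfg, "prep", arts)
    log.info("prep: kept %s, dropped %s", kept, diag_doc["dropped"])
    return arts


def stage_optimize(cfg: PipelineConfig) -> list[str]:
    covs = _load_covariates(cfg)
    gd = _load_fst(cfg)
    sites = _load_sites(cfg)
    cands = enumerate_candidates(list(covs), max_subset_size=cfg["max_subset_size"])
    sdir = cfg.out_dir / "optimize"
    sdir.mkdir(parents=True, exist_ok=True)
    results_doc: dict = {"candidates": {}}
    arts = []
    for ci, cand in enumerate(m for m in cands.models if m.kind == "surface"):
        ga = GAConfig(**cfg["ga"], seed=_stage_seed(cfg, 10, ci))
        runs, summary = replicate_runs(
            [covs[n] for n in cand.covariates], gd, sites, ga
        )
        results_doc["candidates"][cand.name] = {
            "covariates": list(cand.covariates),
            "summary": summary,
            "runs": [
                {
                    "seed": r.seed,
                    "model": r.model.to_dict(),
                    "fit": r.fit.to_dict(),
                    "n_evaluations": r.n_evaluations,
                }
                for r in runs
            ],
        }
        trace = pd.DataFrame(
            {f"run{k}": pd.Series(r.trace) for k, r in enumerate(runs)}
        )
        tpath = sdir / f"trace_{cand.name.replace('+', '_')}.csv"
        trace.to_csv(tpath, index_label="generation")
        arts.append(str(tpath))
        log.info("optimize[%s]: best logLik %.2f over %d runs", cand.name,
                 max(r.fit.logLik for r in runs), len(runs))
    with open(sdir / "results.json", "w") as fh:
        json.dump(results_doc, fh, indent=2)
    arts.append(str(sdir / "results.json"))
    _write_manifest(cfg, "optimize", arts)
    return arts


def _candidate_distances(
    cfg: PipelineConfig, covs, gd, sites
) -> tuple[dict, dict, dict]:
    """Best-run surface models, their distance matrices, and run-wise fits."""
    rpath = cfg.out_dir / "optimize" / "results.json"
    if not rpath.exists():
        raise FileNotFoundError(f"{rpath} not found; run 'optimize' first")
    with open(rpath) as fh:
        results = json.load(fh)
    ids = list(gd.index)
    ibd = ibd_surface(next(iter(covs.values())))
    graph = build_transition_graph(ibd)
    nodes = sites_to_nodes(graph, sites)
    dists = {"distance": pd.DataFrame(
        commute_distance_matrix(graph, nodes), index=ids, columns=ids
    )}
    best_models: dict[str, SurfaceModel] = {}
    run_fits: dict[str, list] = {}
    for name, doc in results["candidates"].items():
        runs = doc["runs"]
        best = max(runs, key=lambda r: r["fit"]["logLik"])
        model = SurfaceModel.from_dict(best["model"])
        best_models[name] = model
        run_fits[name] = runs
        surf = surface_from_model(model, covs)
        g = build_transition_graph(surf)
        dists[name] = pd.DataFrame(
            commute_distance_matrix(g, sites_to_nodes(g, sites)),
            index=ids, columns=ids,
        )
    return best_models, dists, run_fits


def stage_select(cfg: PipelineConfig) -> list[str]:
    covs = _load_covariates(cfg)
    gd = _load_fst(cfg)
    sites = _load_sites(cfg)
    best_models, dists, run_fits = _candidate_distances(cfg, covs, gd, sites)

    fits = {"null": fit_mlpe(build_design(gd, {}))}
    fits["distance"] = fit_mlpe(build_design(gd, {"distance": dists["distance"]}))
    boot_cands = [
        BootstrapCandidate("null", (), 0),
        BootstrapCandidate("distance", ("distance",), 0),
    ]
    for name, model in best_models.items():
        fits[name] = fit_mlpe(
            build_design(gd, {name: dists[name]}), n_optimized=len(model.parts)
        )
        boot_cands.append(BootstrapCandidate(name, (name,), len(model.parts)))

    report = rank_models(fits, delta_threshold=2.0)
    boot = bootstrap_ranking(
        gd, dists, boot_cands,
        frac=cfg["bootstrap"]["frac"],
        n_boot=cfg["bootstrap"]["n_boot"],
        seed=_stage_seed(cfg, 20),
    )
    table = report.table.join(boot[["bootstrap_pct", "mean_rank"]])
    sdir = cfg.out_dir / "select"
    sdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(sdir / "selection.csv")
    doc = {
        "top_models": report.top_models,
        "delta_threshold": 2.0,
        "bootstrap": boot.reset_index().to_dict(orient="records"),
        "table": table.reset_index().to_dict(orient="records"),
    }
    with open(sdir / "selection.json", "w") as fh:
        json.dump(doc, fh, indent=2)
    _write_manifest(cfg, "select",
                    [str(sdir / "selection.csv"), str(sdir / "selection.json")])
    log.info("select: top models %s", report.top_models)
    return [str(sdir / "selection.csv")]


def _top_models_per_run(cfg: PipelineConfig, covs, gd, sites) -> list[SurfaceModel]:
    """Per replicate run, the top-ranked (dAICc < 2) surface models."""
    _, dists, run_fits = _candidate_distances(cfg, covs, gd, sites)
    null_aicc = fit_mlpe(build_design(gd, {})).aicc
    ibd_aicc = fit_mlpe(build_design(gd, {"d": dists["distance"]})).aicc
    n_runs = max(len(runs) for runs in run_fits.values())
    chosen: list[SurfaceModel] = []
    for r in range(n_runs):
        aiccs = {"null": null_aicc, "distance": ibd_aicc}
        models_r = {}
        for name, runs in run_fits.items():
            if r < len(runs):
                aiccs[name] = runs[r]["fit"]["AICc"]
                models_r[name] = SurfaceModel.from_dict(runs[r]["model"])
        best = min(aiccs.values())
        for name, a in aiccs.items():
            if a - best < 2.0 and name in models_r:
                chosen.append(models_r[name])
    return chosen


def stage_map(cfg: PipelineConfig) -> list[str]:
    covs = _load_covariates(cfg)
    gd = _load_fst(cfg)
    sites = _load_sites(cfg)
    models = _top_models_per_run(cfg, covs, gd, sites)
    if not models:
        log.warning("map: no surface model reached the top set; using the "
                    "best available surface model")
        best_models, _, _ = _candidate_distances(cfg, covs, gd, sites)
        models = [next(iter(best_models.values()))]
    surfaces = [surface_from_model(m, covs) for m in models]
    avg = average_surfaces(surfaces)
    extent = mcp_buffer_extent(sites, cfg["map"]["mcp_buffer_m"])
    nodes = place_node_grid(extent, cfg["map"]["node_buffer_m"],
                            cfg["map"]["n_nodes"], avg)
    rsp = RSPConfig(theta=cfg["rsp"]["theta"])
    pm = cumulative_passage_map(avg, nodes, rsp, crop_extent=extent)
    corridor = corridor_mask(pm, cfg["corridor_keep_fraction"])
    sdir = cfg.out_dir / "map"
    sdir.mkdir(parents=True, exist_ok=True)
    write_raster(avg.grid, sdir / "average_resistance.asc")
    write_raster(pm.grid, sdir / "present_passages.asc")
    write_raster(corridor, sdir / "corridor.asc")
    doc = {
        "models": [m.to_dict() for m in models],
        "n_nodes": int(nodes.count),
        "node_cells": nodes.cells.tolist(),
        "spacing": nodes.spacing,
        "theta": rsp.theta,
        "n_nodes_used": pm.n_nodes,
    }
    with open(sdir / "mapping.json", "w") as fh:
        json.dump(doc, fh, indent=2)
    arts = [str(sdir / p) for p in
            ("average_resistance.asc", "present_passages.asc", "corridor.asc",
             "mapping.json")]
    _write_manifest(cfg, "map", arts)
    log.info("map: %d nodes, %d replicate-run models averaged", nodes.count,
             len(models))
    return arts


def stage_project(cfg: PipelineConfig) -> list[str]:
    covs = _load_covariates(cfg)
    mdir = cfg.out_dir / "map"
    if not (mdir / "mapping.json").exists():
        raise FileNotFoundError(
            f"{mdir / 'mapping.json'} not found; run 'map' first"
        )
    with open(mdir / "mapping.json") as fh:
        mapping = json.load(fh)
    models = [SurfaceModel.from_dict(d) for d in mapping["models"]]
    future: dict[str, RasterGrid] = {}
    for name, p in cfg["future"]["covariates"].items():
        future[name] = read_raster(p, name=name)
    for name, off in cfg["future"].get("offset", {}).items():
        if name in covs and name not in future:
            g = covs[name]
            future[name] = g.with_values(g.values + off)
    sites = _load_sites(cfg)
    extent = mcp_buffer_extent(sites, cfg["map"]["mcp_buffer_m"])
    avg = average_surfaces([surface_from_model(m, covs) for m in models])
    nodes = NodeGrid(
        coords=np.empty((len(mapping["node_cells"]), 2)),
        cells=np.array(mapping["node_cells"]),
        spacing=mapping["spacing"],
        n_requested=mapping["n_nodes"],
    )
    rsp = RSPConfig(theta=mapping["theta"])
    pm_future = project_future_map(models, future, covs, nodes, rsp, extent)
    present_grid = read_raster(mdir / "present_passages.asc")
    present = PassageMap(grid=present_grid, n_nodes=pm_future.n_nodes,
                         theta=rsp.theta, buffer_cropped=True)
    diff = difference_map(pm_future, present)
    sdir = cfg.out_dir / "project"
    sdir.mkdir(parents=True, exist_ok=True)
    write_raster(pm_future.grid, sdir / "future_passages.asc")
    write_raster(diff, sdir / "difference.asc")
    doc = {
        "swapped_covariates": sorted(future),
        "theta": rsp.theta,
        "n_nodes": pm_future.n_nodes,
    }
    with open(sdir / "projection.json", "w") as fh:
        json.dump(doc, fh, indent=2)
    arts = [str(sdir / p) for p in
            ("future_passages.asc", "difference.asc", "projection.json")]
    _write_manifest(cfg, "project", arts)
    log.info("project: swapped %s", sorted(future))
    return arts


def project_future_map(models, future, static, nodes, rsp, extent):
    from .connectivity_mapping import project_future

    return project_future(models, future, static, nodes, rsp, crop_extent=extent)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fst": stage_fst,
    "prep": stage_prep,
    "optimize": stage_optimize,
    "select": stage_select,
    "map": stage_map,
    "project": stage_project,
}


def run(stage: str, config: dict | PipelineConfig, out_dir=None,
        seed: int | None = None) -> list[str]:
    """Run one pipeline stage (or ``all``); returns the artifact paths."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    if isinstance(config, PipelineConfig):
        cfg = config
    else:
        cfg = validate_config(config, out_dir or config.get("out_dir", "runs"),
                              seed=seed)
    if stage == "all":
        arts = []
        for s in STAGES[:-1]:
            arts += _STAGE_FUNCS[s](cfg)
        return arts
    return _STAGE_FUNCS[stage](cfg)
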