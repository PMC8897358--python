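"""Genetic-algorithm optimization of resistance surfaces.

Searches, per covariate, over the eight transformation families and their
(shape, max-resistance) parameters, scoring each candidate composite
surface by the MLPE log-likelihood of its commute-distance predictor
against the pairwise genetic distances. The chromosome holds three genes
per covariate — a continuous family gene rounded at decode, log10(shape)
and log10(max resistance) — and evolves under an elitist GA with
tournament selection, blend (BLX) crossover and bounded Gaussian
mutation, so the best objective per generation is non-decreasing.

Because the search is stochastic, the whole optimization is replicated
over independent seeds and the cross-run dispersion of selected families
and parameters is reported.

Graph topology (nodes, edges, center-to-center distances) depends only on
the grid and its mask, so it is built once per optimization and only edge
conductances are recomputed per evaluated chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .effective_distance import TransitionGraph, build_transition_graph, commute_distance_matrix
from .grids import RasterGrid
from .mlpe import MLPEFit, PairDesign, build_design, fit_mlpe
from .raster_prep import assert_grid_consistent
from .resistance_transforms import (
    FAMILIES,
    ResistanceSurface,
    TransformSpec,
    apply_transform,
    compose_surfaces,
    rescale01,
)

__all__ = [
    "GAConfig",
    "OptimizationResult",
    "SurfaceModel",
    "optimize_surface_set",
    "replicate_runs",
    "sites_to_nodes",
    "surface_from_model",
    "ibd_surface",
]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    max_generations: int = 200
    stall_generations: int = 25
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1          # per gene
    s_bounds: tuple[float, float] = (0.01, 10.0)
    m_bounds: tuple[float, float] = (1.01, 2500.0)
    seed: int = 0
    n_replicate_runs: int = 10
    tournament_size: int = 3

    def __post_init__(self) -> None:
        if self.population_size < 10:
            raise ValueError("population_size must be >= 10")
        if self.s_bounds[0] <= 0 or self.m_bounds[0] <= 1:
            raise ValueError("shape bounds must be positive and m_min > 1")
        if self.n_replicate_runs < 1:
            raise ValueError("n_replicate_runs must be >= 1")


@dataclass
class SurfaceModel:
    """A fitted resistance model: one TransformSpec per covariate plus the
    covariate calibration bounds (raw min/max used for the [0,1] rescale),
    needed to re-apply the transformation to scenario rasters."""

    parts: list[tuple[str, TransformSpec, tuple[float, float]]]

    def to_dict(self) -> dict:
        return {
            "parts": [
                {"covariate": n, **t.to_dict(), "calibration": list(b)}
                for n, t, b in self.parts
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceModel":
        return cls(parts=[
            (p["covariate"], TransformSpec(p["family"], p["shape"], p["max"]),
             tuple(p["calibration"]))
            for p in d["parts"]
        ])


@dataclass
class OptimizationResult:
    model: SurfaceModel
    fit: MLPEFit
    trace: np.ndarray            # best objective per generation (non-decreasing)
    seed: int
    n_evaluations: int
    covariate_names: list[str] = field(default_factory=list)


def sites_to_nodes(graph: TransitionGraph, sites: pd.DataFrame) -> np.ndarray:
    spec = graph.surface.grid.spec
    return np.array([
        graph.node_at(*spec.cell_of(x, y)) for x, y in zip(sites["x"], sites["y"])
    ])


def ibd_surface(template: RasterGrid) -> ResistanceSurface:
    """Uniform resistance-1 surface: the isolation-by-distance model."""
    return ResistanceSurface(
        template.with_values(np.ones_like(template.values), name="ibd"),
        provenance={"covariate": "ibd"},
    )


def surface_from_model(
    model: SurfaceModel, covariates: dict[str, RasterGrid]
) -> ResistanceSurface:
    """Rebuild a resistance surface from stored transformation parameters.

    Raw covariates are rescaled with the stored calibration bounds (values
    outside clip to [0, 1]) so the same model can be applied to scenario
    rasters on the analysis grid.
    """
    parts = []
    for name, t, (lo, hi) in model.parts:
        if name not in covariates:
            raise ValueError(f"model requires covariate {name!r}, not supplied")
        g = covariates[name]
        r01 = np.clip((g.values - lo) / (hi - lo), 0.0, 1.0)
        parts.append(apply_transform(g.with_values(r01), t))
    surface, _ = compose_surfaces(parts)
    return surface


class _Objective:
    """Chromosome -> MLPE logLik, with cached graph topology."""

    def __init__(self, covariates, gd, sites, cfg: GAConfig):
        assert_grid_consistent(covariates)
        self.cfg = cfg
        self.names = [g.name for g in covariates]
        self.scaled = [rescale01(g) for g in covariates]
        self.bounds = [
            (float(g.valid_values().min()), float(g.valid_values().max()))
            for g in covariates
        ]
        self.gd = gd
        template = ibd_surface(covariates[0])
        self.topology = build_transition_graph(template)
        self.sites = sites_to_nodes(self.topology, sites)
        # distances per edge recoverable from the uniform surface: R=1 so
        # cost equals center-to-center distance
        self.edge_dist = self.topology.cost.copy()
        self.n_evals = 0

    def decode(self, chrom: np.ndarray) -> SurfaceModel:
        parts = []
        for i, name in enumerate(self.names):
            u, gs, gm = chrom[3 * i: 3 * i + 3]
            fam = FAMILIES[min(int(u), len(FAMILIES) - 1)]
            parts.append((
                name,
                TransformSpec(fam, 10.0 ** gs, 10.0 ** gm),
                self.bounds[i],
            ))
        return SurfaceModel(parts)

    def resistance(self, model: SurfaceModel) -> np.ndarray:
        total = None
        for (_, t, _), g01 in zip(model.parts, self.scaled):
            s = apply_transform(g01, t)
            total = s.grid.values if total is None else total + s.grid.values
        return total

    def graph_for(self, resistance: np.ndarray) -> TransitionGraph:
        topo = self.topology
        ra = resistance[topo.cells[topo.edge_i, 0], topo.cells[topo.edge_i, 1]]
        rb = resistance[topo.cells[topo.edge_j, 0], topo.cells[topo.edge_j, 1]]
        return replace(
            topo,
            conductance=0.5 * (1.0 / ra + 1.0 / rb) / self.edge_dist,
            cost=self.edge_dist * 0.5 * (ra + rb),
        )

    def design_for(self, resistance: np.ndarray, name: str = "dist") -> PairDesign:
        g = self.graph_for(resistance)
        C = commute_distance_matrix(g, self.sites)
        ids = list(self.gd.index)
        dist = pd.DataFrame(C, index=ids, columns=ids)
        return build_design(self.gd, {name: dist})

    def __call__(self, chrom: np.ndarray) -> float:
        self.n_evals += 1
        try:
            model = self.decode(chrom)
            d = self.design_for(self.resistance(model))
            return fit_mlpe(d, n_optimized=len(model.parts)).logLik
        except (ValueError, np.linalg.LinAlgError, RuntimeError):
            return -np.inf


def _gene_bounds(cfg: GAConfig, n_cov: int) -> tuple[np.ndarray, np.ndarray]:
    lo = np.tile([0.0, np.log10(cfg.s_bounds[0]), np.log10(cfg.m_bounds[0])], n_cov)
    hi = np.tile(
        [len(FAMILIES) - 1e-9, np.log10(cfg.s_bounds[1]), np.log10(cfg.m_bounds[1])],
        n_cov,
    )
    return lo, hi


def optimize_surface_set(
    covariates: list[RasterGrid],
    gd: pd.DataFrame,
    sites: pd.DataFrame,
    cfg: GAConfig,
    seed: int | None = None,
) -> OptimizationResult:
    """One elitist GA run over the joint transformation space of ``covariates``."""
    obj = _Objective(covariates, gd, sites, cfg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lo, hi = _gene_bounds(cfg, len(covariates))
    n_genes = len(lo)
    pop = rng.uniform(lo, hi, size=(cfg.population_size, n_genes))
    fitness = np.array([obj(c) for c in pop])
    trace = [float(fitness.max())]
    best_i = int(np.argmax(fitness))
    best = (pop[best_i].copy(), float(fitness[best_i]))
    stall = 0
    sd = 0.15 * (hi - lo)

    for _gen in range(cfg.max_generations):
        new = [best[0].copy()]  # elitism
        while len(new) < cfg.population_size:
            pa = _tournament(pop, fitness, rng, cfg.tournament_size)
            pb = _tournament(pop, fitness, rng, cfg.tournament_size)
            if rng.random() < cfg.crossover_prob:
                alpha = rng.uniform(-0.5, 1.5, size=n_genes)
                child = pa + alpha * (pb - pa)
            else:
                child = pa.copy()
            mut = rng.random(n_genes) < cfg.mutation_prob
            child = child + mut * rng.normal(0.0, sd)
            new.append(np.clip(child, lo, hi))
        pop = np.array(new)
        fitness = np.array([obj(c) for c in pop])
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best[1]:
            best = (pop[gen_best].copy(), float(fitness[gen_best]))
            stall = 0
        else:
            stall += 1
        trace.append(best[1])
        if stall >= cfg.stall_generations:
            break

    model = obj.decode(best[0])
    fit = fit_mlpe(obj.design_for(obj.resistance(model)), n_optimized=len(model.parts))
    return OptimizationResult(
        model=model,
        fit=fit,
        trace=np.array(trace),
        seed=int(cfg.seed if seed is None else seed),
        n_evaluations=obj.n_evals,
        covariate_names=list(obj.names),
    )


def _tournament(pop, fitness, rng, k) -> np.ndarray:
    idx = rng.integers(0, len(pop), size=k)
    return pop[idx[np.argmax(fitness[idx])]]


def replicate_runs(
    covariates: list[RasterGrid],
    gd: pd.DataFrame,
    sites: pd.DataFrame,
    cfg: GAConfig,
) -> tuple[list[OptimizationResult], dict]:
    """Independent GA replicate runs plus a cross-run dispersion summary."""
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=cfg.n_replicate_runs)
    results = [
        optimize_surface_set(covariates, gd, sites, cfg, seed=int(s)) for s in seeds
    ]
    summary: dict = {"seeds": seeds.tolist(), "n_runs": len(results)}
    lls = [r.fit.logLik for r in results]
    summary["logLik_mean"] = float(np.mean(lls))
    summary["logLik_sd"] = float(np.std(lls, ddof=1)) if len(lls) > 1 else 0.0
    per_cov: dict = {}
    for i, name in enumerate(results[0].covariate_names):
        fams = [r.model.parts[i][1].family for r in results]
        shapes = [r.model.parts[i][1].shape for r in results]
        maxes = [r.model.parts[i][1].max_resistance for r in results]
        per_cov[name] = {
            "families": {f: fams.count(f) for f in sorted(set(fams))},
            "shape_mean": float(np.mean(shapes)),
            "shape_sd": float(np.std(shapes, ddof=1)) if len(shapes) > 1 else 0.0,
            "max_mean": float(np.mean(maxes)),
            "max_sd": float(np.std(maxes, ddof=1)) if len(maxes) > 1 else 0.0,
        }
    summary["covariates"] = per_cov
    return results, summary
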