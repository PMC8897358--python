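"""Synthetic landscapes with the statistical structure the analysis assumes.

Generates, at desk scale, everything the pipeline consumes: spatially
autocorrelated covariate rasters (stationary Gaussian random fields built
by circulant embedding of an exponential covariance), a sampling-site
layout, a known true resistance transformation, pairwise genetic
distances drawn from the exact MLPE generative model, and genotype
matrices whose pairwise Fst increases with resistance distance.

The genotype model is a correlated Balding–Nichols approximation, not a
coalescent: per locus an ancestral frequency p ~ U(0.1, 0.9) is drawn,
population frequencies get Balding–Nichols Beta(p(1-F)/F, (1-p)(1-F)/F)
marginals with divergence F = ``fst_scale``, coupled across populations
through a Gaussian copula with correlation exp(-d_kl / phi) so that
nearby (low resistance distance) populations stay similar. Genotypes are
Binomial(2, freq). Only the Fst estimator and its monotone response to
resistance distance are under test, not population-genetic realism.

Defaults mirror the scale of the study design the pipeline targets
(24 sampling sites, ~20 diploids per site, thousands of SNPs, 5 km cells)
reduced to sizes that run in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm
from shapely.geometry import Point, Polygon, box

from .genetics import GenotypeMatrix, write_genalex
from .grids import GridSpec, RasterGrid
from .raster_prep import write_raster
from .resistance_transforms import (
    ResistanceSurface,
    TransformSpec,
    apply_transform,
    compose_surfaces,
    rescale01,
)

__all__ = [
    "SyntheticConfig",
    "generate_covariate_stack",
    "generate_sites",
    "build_true_resistance",
    "simulate_genetic_distances",
    "simulate_genotypes",
    "write_synthetic_dataset",
]

_COVARIATE_RANGES = {
    "precipitation": (20.0, 120.0),   # mean daily July precipitation, mm
    "host_cover": (0.0, 100.0),       # % host-species cover per cell
    "temperature": (12.0, 22.0),      # mean July temperature, degC
    "wind_speed": (2.0, 10.0),        # m/s at flight altitude
    "elevation": (0.0, 800.0),        # m a.s.l.
}
_DEFAULT_NAMES = list(_COVARIATE_RANGES)


@dataclass
class SyntheticConfig:
    n_rows: int = 50
    n_cols: int = 50
    cell_size: float = 5000.0
    n_covariates: int = 2
    autocorr_range: float = 50_000.0       # Gaussian-field correlation length, m
    covariate_corr: float = 0.0            # target pairwise field correlation
    n_sites: int = 24
    true_model: list[tuple[str, TransformSpec]] = dc_field(
        default_factory=lambda: [
            ("precipitation", TransformSpec("Inverse Monomolecular", 0.3, 100.0)),
        ]
    )
    beta0: float = 0.05                    # mean pairwise genetic distance
    beta1: float = 0.02                    # slope on standardized eff. distance
    sigma_u: float = 0.0125                # population random-effect sd
    sigma_e: float = 0.0155                # residual pair sd
    n_loci: int = 2000
    n_individuals_per_site: int = 20
    fst_scale: float = 0.1                 # Balding–Nichols divergence at range
    phi: float | None = None               # copula corr length; default mean(d)
    covariate_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_rows", "n_cols", "n_covariates", "n_sites", "n_loci",
                     "n_individuals_per_site"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (self.cell_size > 0):
            raise ValueError("cell_size must be positive")
        if not (self.autocorr_range > 0):
            raise ValueError("autocorr_range must be positive")
        if not (0 <= self.covariate_corr < 1):
            raise ValueError("covariate_corr must lie in [0, 1)")
        if self.sigma_u < 0 or self.sigma_e < 0:
            raise ValueError("sigma_u and sigma_e must be non-negative")
        if not (0 < self.fst_scale < 1):
            raise ValueError("fst_scale must lie in (0, 1)")

    @property
    def grid_spec(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, 0.0,
                        self.n_rows * self.cell_size, self.cell_size)

    def names(self) -> list[str]:
        if self.covariate_names:
            if len(self.covariate_names) != self.n_covariates:
                raise ValueError("covariate_names length must equal n_covariates")
            return list(self.covariate_names)
        reps = -(-self.n_covariates // len(_DEFAULT_NAMES))
        pool = []
        for r in range(reps):
            for n in _DEFAULT_NAMES:
                pool.append(n if r == 0 else f"{n}_{r + 1}")
        return pool[: self.n_covariates]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


def _gaussian_field(
    n_rows: int, n_cols: int, cell_size: float, corr_range: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Standardized stationary field, Corr(h) = exp(-h / corr_range).

    Circulant embedding on a doubled torus; any (rare) negative embedding
    eigenvalues are clipped, a standard approximation.
    """
    mr, mc = 2 * n_rows, 2 * n_cols
    ir = np.minimum(np.arange(mr), mr - np.arange(mr))
    ic = np.minimum(np.arange(mc), mc - np.arange(mc))
    h = np.hypot.outer(ir, ic) * cell_size
    cov = np.exp(-h / corr_range)
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    noise = rng.standard_normal((mr, mc)) + 1j * rng.standard_normal((mr, mc))
    f = np.fft.fft2(np.sqrt(lam / (mr * mc)) * noise).real[:n_rows, :n_cols]
    f = (f - f.mean()) / f.std()
    return f


def generate_covariate_stack(cfg: SyntheticConfig) -> list[RasterGrid]:
    """Correlated Gaussian-random-field covariates on the shared grid.

    Pairwise field correlation targets ``covariate_corr`` through a shared
    common factor; each field is affinely rescaled to a plausible physical
    range for its covariate name (affine, so correlations are preserved).
    """
    rng = cfg._rng(1)
    spec = cfg.grid_spec
    common = _gaussian_field(cfg.n_rows, cfg.n_cols, cfg.cell_size,
                             cfg.autocorr_range, rng)
    rho = cfg.covariate_corr
    grids = []
    for name in cfg.names():
        own = _gaussian_field(cfg.n_rows, cfg.n_cols, cfg.cell_size,
                              cfg.autocorr_range, rng)
        z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * own
        base = name.split("_")[0] if name.split("_")[-1].isdigit() else name
        lo, hi = _COVARIATE_RANGES.get(base, (0.0, 1.0))
        v = lo + (hi - lo) * (z - z.min()) / (z.max() - z.min())
        grids.append(RasterGrid(v, spec, mask=np.zeros_like(v, bool), name=name))
    return grids


def generate_sites(
    cfg: SyntheticConfig, extent: Polygon | None = None,
    valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sampling sites on distinct cell centers inside ``extent``.

    Minimum pairwise separation is 2 cell sizes; sites never fall on
    nodata cells (pass ``valid`` to mask cells out).
    """
    spec = cfg.grid_spec
    if extent is None:
        xmin, ymin, xmax, ymax = spec.bounds
        extent = box(xmin, ymin, xmax, ymax)
    gx, gy = spec.cell_centers()
    ok = np.ones(gx.shape, bool) if valid is None else np.asarray(valid, bool)
    cand = [
        (x, y)
        for x, y, o in zip(gx.ravel(), gy.ravel(), ok.ravel())
        if o and extent.contains(Point(x, y))
    ]
    if len(cand) < cfg.n_sites:
        raise ValueError(
            f"extent holds only {len(cand)} candidate cells for "
            f"{cfg.n_sites} sites"
        )
    rng = cfg._rng(2)
    order = rng.permutation(len(cand))
    min_sep = 2.0 * cfg.cell_size
    chosen: list[tuple[float, float]] = []
    for k in order:
        x, y = cand[k]
        if all(np.hypot(x - cx, y - cy) >= min_sep for cx, cy in chosen):
            chosen.append((x, y))
            if len(chosen) == cfg.n_sites:
                break
    if len(chosen) < cfg.n_sites:
        raise ValueError(
            f"could not place {cfg.n_sites} sites with separation "
            f">= {min_sep} m inside the extent"
        )
    return pd.DataFrame(
        {
            "site": [f"S{i + 1:02d}" for i in range(cfg.n_sites)],
            "x": [c[0] for c in chosen],
            "y": [c[1] for c in chosen],
            "n": cfg.n_individuals_per_site,
        }
    )


def build_true_resistance(
    cfg: SyntheticConfig, covariates: list[RasterGrid]
) -> ResistanceSurface:
    """Apply the configured true transformations and compose the surfaces."""
    by_name = {g.name: g for g in covariates}
    parts = []
    for name, t in cfg.true_model:
        if name not in by_name:
            raise ValueError(f"true_model names unknown covariate {name!r}")
        parts.append(apply_transform(rescale01(by_name[name]), t))
    surface, _ = compose_surfaces(parts)
    return surface


def _check_square(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, rtol=0, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix must be finite")
    return d


def simulate_genetic_distances(
    cfg: SyntheticConfig, dist: np.ndarray | pd.DataFrame
) -> pd.DataFrame:
    """Pairwise genetic distances from the exact MLPE generative model.

    y_ij = beta0 + beta1 * z(d_ij) + u_i + u_j + eps_ij with z the
    centered/scaled upper-triangle distances, u per-population effects and
    eps per-pair noise.
    """
    ids = list(dist.index) if isinstance(dist, pd.DataFrame) else None
    d = _check_square(dist.to_numpy() if isinstance(dist, pd.DataFrame) else dist)
    n = d.shape[0]
    if ids is None:
        ids = [f"S{i + 1:02d}" for i in range(n)]
    iu = np.triu_indices(n, k=1)
    x = d[iu]
    z = (x - x.mean()) / x.std() if x.std() > 0 else np.zeros_like(x)
    rng = cfg._rng(3)
    u = rng.normal(0.0, cfg.sigma_u, size=n)
    eps = rng.normal(0.0, cfg.sigma_e, size=len(x))
    y = cfg.beta0 + cfg.beta1 * z + u[iu[0]] + u[iu[1]] + eps
    out = np.zeros_like(d)
    out[iu] = y
    out = out + out.T
    return pd.DataFrame(out, index=ids, columns=ids)


def simulate_genotypes(
    cfg: SyntheticConfig, dist: np.ndarray | pd.DataFrame
) -> GenotypeMatrix:
    """Genotypes whose pairwise Fst increases with resistance distance."""
    ids = list(dist.index) if isinstance(dist, pd.DataFrame) else None
    d = _check_square(dist.to_numpy() if isinstance(dist, pd.DataFrame) else dist)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    n_pops = d.shape[0]
    if ids is None:
        ids = [f"S{i + 1:02d}" for i in range(n_pops)]
    iu = np.triu_indices(n_pops, k=1)
    phi = cfg.phi if cfg.phi is not None else (d[iu].mean() if len(iu[0]) else 1.0)
    corr = np.exp(-d / max(phi, 1e-300))
    np.fill_diagonal(corr, 1.0)
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(n_pops))

    rng = cfg._rng(4)
    F = cfg.fst_scale
    p_anc = rng.uniform(0.1, 0.9, size=cfg.n_loci)
    zmat = (L @ rng.standard_normal((n_pops, cfg.n_loci)))  # (n_pops, n_loci)
    u = norm.cdf(zmat)
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    freqs = beta_dist.ppf(u, a[None, :], b[None, :])
    freqs = np.clip(freqs, 1e-12, 1.0 - 1e-12)

    n_ind = cfg.n_individuals_per_site
    dosages = np.empty((n_pops * n_ind, cfg.n_loci))
    pops = np.empty(n_pops * n_ind, dtype=object)
    for k in range(n_pops):
        sl = slice(k * n_ind, (k + 1) * n_ind)
        dosages[sl] = rng.binomial(2, freqs[k][None, :], size=(n_ind, cfg.n_loci))
        pops[sl] = ids[k]
    return GenotypeMatrix(
        dosages=dosages,
        populations=pops,
        locus_ids=[f"L{j + 1:04d}" for j in range(cfg.n_loci)],
    )


def write_synthetic_dataset(cfg: SyntheticConfig, outdir) -> dict:
    """Generate and write a full synthetic dataset; returns the manifest.

    Writes covariates (.asc), sites (CSV), genotypes (simplified Genalex
    CSV) and the truth parameters (JSON sidecar). The genetic response is
    genotype-derived Fst, so the whole pipeline (Fst on up) is exercised.
    """
    from .effective_distance import build_transition_graph, commute_distance_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    covariates = generate_covariate_stack(cfg)
    sites = generate_sites(cfg)
    truth = build_true_resistance(cfg, covariates)
    graph = build_transition_graph(truth)
    nodes = np.array([
        graph.node_at(*cfg.grid_spec.cell_of(x, y))
        for x, y in zip(sites["x"], sites["y"])
    ])
    dmat = commute_distance_matrix(graph, nodes)
    dist = pd.DataFrame(dmat, index=sites["site"], columns=sites["site"])
    genotypes = simulate_genotypes(cfg, dist)
    gdist = simulate_genetic_distances(cfg, dist)

    paths = {}
    for g in covariates:
        p = outdir / f"covariate_{g.name}.asc"
        write_raster(g, p)
        paths[g.name] = str(p)
    sites.to_csv(outdir / "sites.csv", index=False)
    write_genalex(genotypes, outdir / "genotypes.csv")
    gdist.to_csv(outdir / "true_genetic_distances.csv")
    dist.to_csv(outdir / "true_resistance_distances.csv")
    truth_doc = {
        "true_model": [
            {"covariate": name, **t.to_dict()} for name, t in cfg.true_model
        ],
        "beta0": cfg.beta0,
        "beta1": cfg.beta1,
        "sigma_u": cfg.sigma_u,
        "sigma_e": cfg.sigma_e,
        "fst_scale": cfg.fst_scale,
        "seed": cfg.seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=2)
    manifest = {
        "covariates": paths,
        "sites": str(outdir / "sites.csv"),
        "genotypes": str(outdir / "genotypes.csv"),
        "truth": str(outdir / "truth.json"),
    }
    return manifest
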