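# resistscape

Landscape-genetics inference of movement resistance, and connectivity
mapping, for populations sampled on a raster landscape.

The question the package answers: **which environmental layers impede or
facilitate gene flow, how strongly, and where do the resulting movement
corridors lie — today and under a climate scenario?** It is aimed at
landscape geneticists and spatial ecologists working with SNP data from
georeferenced sampling sites plus raster covariates (climate, host cover,
elevation, ...), in planar projected coordinates.

## The method

1. **Genetic distances.** Pairwise population differentiation is the
   Weir–Cockerham (1984) θ, combined across loci as a ratio of sums,

   θ̂ = Σₗ aₗ / Σₗ (aₗ + bₗ + cₗ),

   with a, b, c the among-population, among-individual and within-
   individual variance components. Negative estimates are retained.

2. **Resistance surfaces.** Each covariate, rescaled to [0, 1], passes
   through one of eight two-parameter exponential transformations
   (Monomolecular 1 − e^(−r/s) and Ricker r·e^(−r/s) bases, each plain /
   Reverse / Inverse / Inverse-Reverse), then is affinely mapped onto
   [1, m]. Composite surfaces sum cell resistances; each part's percent
   contribution to the per-cell travel cost is reported.

3. **Effective distances.** Valid cells become an 8-neighbor graph with
   edge conductance mean(1/Rᵢ, 1/Rⱼ)/distance. The optimization stage
   uses random-walk commute distances C(i,j) = vol(G)·R_eff(i,j) from
   grounded graph-Laplacian solves.

4. **MLPE regression.** Genetic distances are regressed on standardized
   effective distances with a random intercept per population (two per
   pair), y = Xβ + Zu + ε, u ~ N(0, σ²ᵤI), ε ~ N(0, σ²ₑI), fit by
   profile maximum likelihood. Models are compared by AICc (sample size
   = number of populations) and summarized by marginal / conditional R².

5. **Optimization and selection.** A seeded elitist genetic algorithm
   searches transformation families and parameters to maximize the MLPE
   log-likelihood, with replicate runs; candidates (every covariate
   subset, plus intercept-only null and distance-only models) are ranked
   by ΔAICc < 2 and rank stability is assessed by repeatedly refitting on
   75% population subsamples.

6. **Connectivity mapping.** Randomized shortest paths interpolate
   between circuit-style random walks (θ → 0) and least-cost paths
   (θ large). At the default θ = 10⁻⁶ net passages are computed exactly
   as circuit flows. Passages are summed over all pairs of a regular node
   lattice in a buffered extent, the buffer is cropped, and the top 50%
   of values defines the corridor. Scenario projection re-applies the
   stored transformation parameters with a covariate swapped (e.g.
   future precipitation, host cover held constant) and maps the
   future − present difference.

A synthetic-landscape generator (Gaussian random-field covariates, a
known true transformation, MLPE-structured genetic distances, and
correlated Balding–Nichols genotypes whose pairwise Fst grows with
resistance distance) makes every stage testable at desk scale.

## Worked example

Recover a known resistance model from synthetic data:

```python
import pandas as pd
from resistscape import (
    SyntheticConfig, GAConfig, TransformSpec,
    generate_covariate_stack, generate_sites, build_true_resistance,
    build_transition_graph, commute_distance_matrix,
    simulate_genotypes, pairwise_fst,
    optimize_surface_set, build_design, fit_mlpe,
)
from resistscape.optimizer import sites_to_nodes

cfg = SyntheticConfig(
    n_rows=40, n_cols=40, n_sites=20, seed=7, n_covariates=1,
    true_model=[("precipitation",
                 TransformSpec("Inverse Monomolecular", 0.3, 100.0))],
)
covariates = generate_covariate_stack(cfg)
sites = generate_sites(cfg)

truth = build_true_resistance(cfg, covariates)
graph = build_transition_graph(truth)
dist = pd.DataFrame(
    commute_distance_matrix(graph, sites_to_nodes(graph, sites)),
    index=sites.site, columns=sites.site)
genotypes = simulate_genotypes(cfg, dist)
fst, meta = pairwise_fst(genotypes)
print(f"mean pairwise Fst: {fst.values.sum() / (20 * 19):.4f} "
      f"({meta['n_negative']} negative estimates)")

ga = GAConfig(population_size=20, max_generations=25, stall_generations=10)
result = optimize_surface_set(covariates, fst, sites, ga, seed=1)
name, spec, _ = result.model.parts[0]
print(f"selected transformation: {spec.family} "
      f"(shape={spec.shape:.2f}, max={spec.max_resistance:.0f})")
print(f"logLik={result.fit.logLik:.1f}  AICc={result.fit.aicc:.1f}  "
      f"R2m={result.fit.r2m:.2f}  R2c={result.fit.r2c:.2f}")

null = fit_mlpe(build_design(fst, {}))
print(f"dAICc of intercept-only null: {null.aicc - result.fit.aicc:.1f}")
```

Output:

```
mean pairwise Fst: 0.0621 (0 negative estimates)
selected transformation: Inverse Monomolecular (shape=0.52, max=2500)
logLik=785.4  AICc=-1552.4  R2m=0.93  R2c=0.94
dAICc of intercept-only null: 292.3
```

The GA identifies the true transformation family — cost of movement
falling steeply with precipitation — and the landscape model beats the
intercept-only null by a ΔAICc of 292: the genotype data carry a strong
isolation-by-resistance signal. The shape parameter and maximum
resistance are less sharply identified than the family and direction
(many (s, m) pairs give nearly the same *relative* resistance pattern,
and commute distances only see relative resistance).

## Command-line pipeline

The same stages run behind a CLI with a single JSON config:

```sh
resistscape simulate --config cfg.json --out runs/demo
resistscape all      --config cfg.json --out runs/demo --seed 3
```

Stages: `simulate`, `fst`, `prep` (VIF screen at threshold 2.5,
host-minus-defoliation merge, IDW station interpolation), `optimize`
(GA replicate runs), `select` (AICc ranking + bootstrap), `map`
(cumulative passages, corridor), `project` (scenario swap, difference
map), or `all`. Every stage writes its artifacts plus a manifest
(config hash, seed, versions) under the output directory, and reruns
with the same config and seed are bit-identical.

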