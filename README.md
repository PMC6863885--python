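# ibrscape

Landscape genomics on raster landscapes: does habitat loss reduce genetic
diversity or impede gene flow?

`ibrscape` implements the full analysis chain used to answer that question
for plants sampled across mined and intact habitat: SNP quality control to
a neutral, independent marker set; population structure (cross-validated
ancestry estimation and k-means/BIC clustering); pairwise Yang relatedness,
individual heterozygosity/inbreeding and a permutation correlogram;
buffer-based habitat amount/loss regression with AIC multimodel inference
(GLS with spatial correlation structures, mixed models); isolation by
resistance — genetic-algorithm optimization of resistance surfaces against
maximum-likelihood-population-effects (MLPE) models of relatedness on
circuit-theory distances, compared against the isolation-by-distance
null — and barrier detection with Gabriel graphs and Monmonier's
algorithm. A synthetic-data generator produces multi-year mining
landscapes, sample designs and genotypes with known ground truth, so every
stage is testable without external data.

## The models at the core

**Relatedness.** For individuals *j* ≠ *k* and loci *i* with allele
frequency *p&#7522;* estimated from the sample,

    A_jk = mean_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

the allele-frequency-standardized (GCTA) estimator; it is the response
variable of all gene-flow models.

**Resistance distance.** A resistance surface assigns each raster cell a
cost ≥ 1; the distance between two samples is the effective resistance
between their cells on the 8-neighborhood lattice graph (conductance
1/mean(r_u, r_v) per step, diagonal steps √2 costlier), computed by sparse
Laplacian solves and exact against the dense pseudoinverse formula
R_uv = (e_u − e_v)ᵀ L⁺ (e_u − e_v).

**MLPE.** Pairwise observations are not independent: rows sharing an
individual are correlated. The MLPE covariance σ_u²·AAᵀ + σ_ε²·I (A the
pair-by-individual incidence matrix) induces correlation
ρ = σ_u²/(2σ_u² + σ_ε²) < 0.5 between such rows and is fitted by ML with a
cached spectral decomposition, fast enough to serve as the objective of a
genetic algorithm over surface parameters (per-class resistances, or
shape/maximum of monomolecular and Ricker transformations of continuous
layers). Surfaces of different complexity compete on AICc with their free
parameters charged; whenever the geographic-distance (IBD) model sits
within 2 AIC of the best land-cover model, IBD is declared the most
parsimonious gene-flow model.

## Worked example

```python
from ibrscape.synthgen import make_landscape, sample_locations, simulate_genotypes
from ibrscape.variant_qc import run_qc
from ibrscape.relatedness import yang_relatedness
from ibrscape.resistance import null_ibd_surface, commute_distance
from ibrscape.optimizer import GAConfig, optimize_surface, mlpe_from_distance

# a 40x40 landscape: crescent canga plateau, forest, a mine growing
# 0 -> 80 -> 130 -> 180 cells over the years; true class resistances
# canga 1 < forest 3 < mine 8 shape the simulated gene flow
truth = make_landscape(grid_size=40, seed=1,
                       mine_growth_schedule={1979: 0, 2011: 80, 2014: 130, 2016: 180},
                       cluster_params={"K": 1})
samples = sample_locations(truth, n=30, min_dist=3.0, seed=2)
geno, _ = simulate_genotypes(truth, samples, n_loci=1000,
                             artifact_spec={"missing": 10, "rare": 5}, seed=3)

clean, report = run_qc(geno)
print(report.summary())

rel = yang_relatedness(clean)
ibd = commute_distance(null_ibd_surface(truth.latest_map), samples.coords)
ga = GAConfig(population=20, stagnation=6, max_generations=25, seed=5)
run = optimize_surface(rel, truth.latest_map, "categorical", ga,
                       coords=samples.coords)
print("optimized class resistances:",
      {c: round(v, 1) for c, v in run.best_params["class_values"].items()})
print("AICc, land cover vs IBD null: %.1f vs %.1f"
      % (run.final_objective, mlpe_from_distance(rel, ibd).aicc))
```

prints

```
input loci: 1000
  removed by missingness: 10
  removed by quality: 0
  removed by depth: 0
  removed by maf: 5
  removed by all_heterozygous: 0
  removed by hwe: 0
  removed by ld: 7
surviving loci: 978
optimized class resistances: {0: 6.9, 1: 26.3, 2: 44.8}
AICc, land cover vs IBD null: -1774.6 vs -1721.7
```

The QC removed exactly the 10 planted high-missingness and 5 planted rare
loci (plus 7 incidentally correlated pairs). The optimizer recovered the
true resistance *ordering* — canga (class 0, 6.9) most permeable, then
forest (26.3), then mine (44.8) — and the land-cover model beats the IBD
null by ~53 AICc units, correctly detecting isolation by resistance.
Absolute resistance values are identified only up to a monotone stretch
(circuit distances saturate), which is why convergence checks and model
ranking, not raw values, carry the inference.

The same pipeline runs end-to-end from a YAML config:

```
ibrscape run config.yaml --out results/
```

with subcommands (`simulate`, `qc`, `structure`, `relatedness`,
`landscape`, `resist`, `optimize`, `barriers`, ...) for individual stages
on files.

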