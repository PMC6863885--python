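# Methods

This note documents the models and procedures implemented in `ibrscape`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data generator does and does not emulate.

## The analysis the package implements

The package addresses a standard landscape-genomics question: does habitat
loss on a mapped landscape reduce genetic diversity or impede gene flow?
The analysis chain is:

1. **SNP quality control** to a neutral, independent marker set;
2. **population structure** (ancestry coefficients, choice of the number of
   clusters K, a complementary k-means clustering);
3. **relatedness and diversity** (pairwise Yang relatedness, individual
   heterozygosity H and inbreeding f, a spatial autocorrelation
   correlogram);
4. **habitat amount/loss regression** of H and f on buffer-based landscape
   metrics, with AIC multimodel inference;
5. **isolation by resistance**: genetic-algorithm optimization of
   resistance surfaces against an MLPE objective using circuit-theory
   distances, then two-stage gene-flow model comparison against the
   isolation-by-distance (IBD) null;
6. **barrier detection** with Gabriel graphs and Monmonier's algorithm.

## Quality control

Loci are removed, in a fixed recorded order, when: missingness > 30%; site
phred quality <= 50; mean depth outside 30–240; minor-allele frequency
< 3%; every sample heterozygous (a collapsed-paralog signature); the exact
Hardy–Weinberg test gives P < 1e-4; squared pairwise dosage correlation
(pairwise-complete) >= 0.6 with a retained locus; or the differentiation
outlier scan flags the locus. Counts per rule depend on the order, which is
why the report records it. Missing genotypes are filtered on, never
imputed.

The HWE test is the exact conditional test: given the allele counts, the
two-sided p-value sums the probabilities of all heterozygote counts whose
probability does not exceed the observed one. LD pruning is global (the
loci are anonymous reduced-representation tags with no chromosomal
ordering) and greedy: the worst pair loses its more-missing member (ties:
the larger index).

The outlier scan computes per-locus F_ST from cluster allele frequencies
weighted by mean ancestry, F = 1 − Σ_k w_k p_k(1−p_k) / (p̄(1−p̄)), converts
it to z² = F·(n_alleles − K)/(1 − F) — for small F this is the classical
chi-square test of allele-frequency homogeneity with K−1 df, with
n_alleles the average number of called alleles — and recalibrates by the
deterministic genomic-control factor λ = median(z²)/median(χ²_{K−1})
before Benjamini–Hochberg control at Q = 0.05. λ is reported; values far
above 1 mean genome-wide background differentiation, which is exactly what
the genomic control absorbs. A trial-and-error λ calibration used in some
workflows is deliberately replaced by this deterministic estimator for
reproducibility.

## Population structure

Ancestry is a regularized nonnegative factorization of one-hot genotypes
(the sparse-NMF scheme): alternating least squares with per-locus
genotype-state normalization of G, a ridge penalty on Q and Euclidean
simplex projection of its rows; sweeps are accepted only when the
penalized objective decreases, so the objective path is monotone, and the
best of several random restarts wins. The ridge default is alpha = 1:
at desk scale the penalty is then negligible relative to the data term but
still regularizes the collinear cluster-frequency directions. (A larger
default of 10 visibly shrinks the between-cluster contrast of Q — mean
maximum ancestry drops from ~0.97 to ~0.92 on a two-cluster F_ST = 0.3
simulation.)

K is chosen by masked-entry cross-validation: a random 10% of non-missing
entries are hidden, the model fitted, and squared error of the imputed
dosage 2·Q·p scored on the hidden entries; the smallest K attaining the
minimal mean error wins. The complementary clustering is k-means on the
principal components explaining >= 90% of variance, scored by
BIC(k) = n·ln(WSS/n) + k·ln(n).

Cluster summaries use hard assignments (maximum ancestry coefficient).
Per-cluster expected heterozygosity averages the unbiased per-locus
2p̂q̂·2n/(2n−1) over loci polymorphic within the cluster; cluster F averages
the per-individual method-of-moments inbreeding computed within the
cluster; 95% CIs are percentile bootstraps over loci.

## Relatedness and the correlogram

Yang (GCTA) relatedness standardizes dosages by the full-sample allele
frequency: A_jk = mean_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i q_i) over loci
where both calls are present, with the bias-corrected own-term on the
diagonal. Because p̂ is estimated from the sample, the standardized scores
sum to zero at every locus and the mean off-diagonal is −1/(n−1) in
expectation, not 0 — tests and downstream interpretation account for this.
Individual H is the observed heterozygosity proportion 1 − O/N (H is later
logit-transformed, so it must live in (0,1)); f = (O − E)/(N − E) with
E the HWE-expected homozygote count. Monomorphic loci are excluded
everywhere (undefined denominators).

The correlogram is a degree-1 LOESS (tricube weights over the
ceil(span·n) nearest points, span 0.75) of pairwise relatedness against
pairwise distance, evaluated on a 50-point grid spanning the 1st–99th
percentile of distances (grid tails are excluded because edge windows make
local-linear fits unstable). The null envelope comes from 999 joint
row/column permutations of the relatedness matrix — preserving symmetry
and the value multiset — refitted on the same grid; pointwise 2.5/97.5
percentiles bound the no-structure expectation.

## Model engine

One marginal-likelihood core serves three model families; beta and sigma²
are always profiled analytically and the remaining variance parameters
optimized numerically, under ML (REML likelihoods are not comparable
across fixed-effect structures, and all downstream inference is
AIC-based). Wald 95% intervals are reported.

* **GLS** with linear, exponential, Gaussian or spherical correlation in
  Euclidean distance, plus optional per-group variance multipliers
  (reference group fixed at 1) for heteroscedasticity. No nugget term.
* **LMM** with one or two crossed random intercepts via profiled variance
  ratios; fits driven to the zero-variance boundary are flagged singular.
* **MLPE** for pairwise data: covariance σ_u²·AAᵀ + σ_ε²·I with A the
  pair-by-individual incidence matrix, inducing correlation
  ρ = σ_u²/(2σ_u² + σ_ε²) ∈ (0, 0.5) between pairs sharing one individual.
  The eigendecomposition of AAᵀ depends only on the pair structure and is
  cached, making each likelihood evaluation O(n·p²) — the resistance
  optimizer evaluates thousands of candidates against one structure.

Multimodel inference follows the ΔAIC ≤ 2 convention: Akaike weights,
plausible set, per-term likelihood-ratio tests, conditional (natural)
model averaging with unconditional standard errors, variable importance as
the renormalized weight sum over plausible models containing the term, and
an all-subsets search that excludes any subset containing a predictor pair
with |r| >= 0.6.

## Resistance surfaces and circuit theory

Categorical surfaces assign one value per land-cover class and are divided
by their minimum (resistances are relative; the most permeable class is
pinned at 1, leaving n_classes − 1 free parameters). Continuous layers are
min-max scaled and passed through monomolecular (1 − e^{−x/shape}) or
Ricker (x·e^{−x/shape}) curves; "reverse" applies the curve to 1 − x and
"inverse" flips it vertically, giving eight variants; the result is
affinely rescaled to [1, maximum] (two free parameters plus the variant).

Distances are effective resistances on the 8-neighborhood lattice graph
with conductance 1/mean(r_u, r_v) for cardinal and 1/(√2·mean) for
diagonal steps (average resistance rather than average conductance for the
cell connection; a config switch in the graph builder). One sparse LU
factorization of the grounded Laplacian serves all source nodes. Commute
time equals total conductance times effective resistance — a single scale
factor per surface — and predictors are standardized before fitting, so
effective resistance is reported as the cheaper, numerically stabler
choice. Every distance matrix is checked for symmetry, zero diagonal and
the triangle inequality.

## Surface optimization and gene-flow comparison

The optimizer is a real-coded GA (tournament size 3, blend crossover 0.8,
bounded Gaussian mutation with SD 10% of each gene's range, elitism 2,
population 50 by default) over log10-scaled surface parameters, stopping
after 25 generations without a 0.01 improvement. Each candidate maps to a
surface, to commute distances, and to a univariate MLPE of relatedness on
the standardized distance; the objective is the model's AICc.

Two conventions matter here and are deliberate:

* **AICc with n = number of individuals, charging surface parameters.**
  Surfaces of different complexity — including the zero-parameter IBD
  null — compete on AICc with the optimized surface parameters included in
  k and the effective sample size set to the number of individuals (pairs
  are heavily dependent). Without this charge, optimizer selection bias
  lets a categorical surface "beat" the IBD null on data simulated without
  any land-cover effect far too often for the IBD-parsimony logic to work.
* **Double-centering of distance predictors.** Yang relatedness is itself
  a centered similarity matrix (allele frequencies are sample-estimated),
  so its expectation under any spatial process is the double-centered
  transform of the underlying kernel. A raw distance predictor therefore
  leaves a large additive row-effect (sample eccentricity) residual that
  rival surfaces can mimic; projecting each distance matrix through the
  Gower centering −HDH/…, then standardizing, aligns the predictor
  geometry with the response and removes that artifact. The generic MLPE
  fitter is unaffected (it accepts any predictors); centering applies in
  the surface-comparison layer.

Gene-flow model selection is two-staged: univariate MLPE models over the
per-year land-cover distances plus geographic (IBD) distance are ranked
first, and whenever IBD sits in the plausible set, isolation by distance
is recorded as the most parsimonious model; the stage-1 land-cover winner
then enters an all-subsets search with all other optimized surfaces
(collinearity screen |r| < 0.6), with LRTs, importance and model-averaged
coefficients. Multi-run convergence is summarized by the CV of final
objectives and pairwise Spearman agreement of recovered parameters.

## Barriers

The connection network is the Gabriel graph (edge when the diametral disc
is empty). Monmonier's algorithm starts at the network edge with maximal
genetic distance and extends in both directions across Delaunay faces,
crossing at each step the face edge with the locally maximal distance;
the default crossing threshold is the mean of network-edge values (between
the background and barrier modes when a genuine discontinuity exists), and
the walk stops at the hull, on a loop, or when no eligible edge remains.
Distances fed to the barrier search are 1 − min-max-scaled relatedness.

## The synthetic-data generator

The generator emulates the study system at desk scale so every stage can
be tested against known truth; all defaults below were calibrated once,
before the test suite was frozen.

* **Landscape.** A crescent-shaped montane-savanna (canga) plateau opening
  east, forest elsewhere, on a 40–60 cell grid. The crescent is
  deliberate: pairs across the bay have a short path through forest, so
  forest resistance is identifiable; a round plateau would leave it
  unconstrained. The mine grows from a fixed cell on the western edge as
  an elongated finger along the crescent spine (open pits follow ore
  bodies), by connectivity-preserving boundary accretion — a cell whose
  removal would split the remaining canga is deferred — so habitat is lost
  without fragmentation, and the pre-mining map has zero mine cells.
* **Samples** sit on canga cells of the most recent map with a minimum
  pairwise spacing (the field rule that avoids collecting close kin).
* **Genotypes.** Ancestral frequencies p ~ U(0.05, 0.95); cluster
  frequencies Balding–Nichols at a target F_ST; ancestry proportions from
  a spatial softmax over K anchor points with scale 0.03 of the sampling
  extent (near-discrete clusters with admixture at contact zones; the
  realized Hudson F_ST then tracks the Balding–Nichols target within
  ~15%). Genotypes are Binomial(2, π) with logit(π) shifted by a
  per-locus Gaussian field η over individuals.
* **The IBR kernel.** η has covariance σ²·K with K the commute-time kernel
  −½·H·D·H (PSD because effective resistance is a negative-type metric),
  normalized to unit mean diagonal, with D the effective-resistance
  distance on the true categorical surface (canga 1, forest 3, mine 8 by
  default) computed by the same code path as inference. Expected
  relatedness is then linear in resistance distance — the relationship
  the MLPE models fit. An exponential kernel σ²·exp(−D/φ) is available
  (`gp_params["kernel"]="exponential"`); it produces a visibly convex
  relatedness–distance relationship that a linear model mis-attributes,
  and is used in tests of the correlogram's power, not as the default.
  σ² defaults to 0.35: strong enough that a 30-sample, 1000-locus dataset
  recovers the class-resistance ordering and rejects IBD decisively, while
  keeping the one-realization structured noise (the realized η sample
  covariance, which rival surfaces can fit) small enough that pure-IBD
  data retain the IBD null — this trade-off is a genuine property of
  single-realization landscape genetics, not an artifact of the
  generator.
* **Planted QC violations** (missingness, low quality, depth extremes,
  rare alleles, all-heterozygous, HWE-violating, LD duplicates,
  differentiation outliers) are injected into disjoint locus sets with
  exact bookkeeping; clean loci that accidentally violate a frequency or
  heterozygosity rule are redrawn, and LD duplicates take the largest
  locus indices so the pruning tie-break removes exactly the planted copy.
  Exact HWE bookkeeping is only guaranteed for unstructured simulations —
  structured data violate a pooled HWE test by construction (the Wahlund
  effect).

What the generator does **not** emulate: read-level errors, linkage along
chromosomes, coalescent genealogies, selection, temporal population
dynamics, and realistic dispersal kernels (the commute-kernel field is a
testability device, not a biological claim). Passing tests therefore
demonstrate that the inference machinery recovers what it assumes, on data
of realistic size and noise — not that those assumptions hold for any
particular species.

## Problem sizes and numerical choices

Simulation-based tests run at 40×40 grids, 30–60 individuals and 200–2000
loci — the scale at which every statistical property checked (recovery,
calibration, negative controls) is comfortably resolved. Spatial
correlation ranges are optimized on a log scale with Nelder–Mead from the
median pairwise distance; non-PD covariances are penalized, not fatal;
MLPE variance ratios use bounded scalar search on log gamma in [−12, 12];
ties in K selection break toward the smaller K; degenerate LOESS windows
fall back to the local weighted mean. All randomness flows through numpy
`SeedSequence` so identical seeds give bit-identical landscapes,
genotypes, and pipeline reports (verified end to end).

## Known limitations

* The MLPE correlation is bounded in (0, 0.5); negative pair correlation
  (which double-centered responses can induce) is not representable.
* The outlier scan assumes the chi-square homogeneity approximation;
  with very small clusters (< ~10 individuals) λ calibration degrades.
* The GA is a global heuristic: convergence across 10 independent runs
  should be checked (the `convergence_check` report) before interpreting
  absolute resistance values; only their ordering and the model ranking
  are stable targets.
* Effective resistance saturates logarithmically with distance on 2-D
  lattices, compressing long-range contrast; this is physical, but it
  means surface parameters far above ~100× the minimum are weakly
  identified (paths simply avoid those cells).
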