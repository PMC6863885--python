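"""Genetic-algorithm optimization of resistance surfaces against an MLPE
objective, multi-run convergence checks, and the two-stage gene-flow model
comparison.

Each candidate parameter vector builds a resistance surface, computes
circuit-theory distances between the samples, standardizes them, and fits
a univariate MLPE regression of pairwise relatedness on distance; the
objective is the model's AIC (lower is better), with the surface's free
parameters included in the penalty so surfaces of different complexity —
including the zero-parameter isolation-by-distance null — compete fairly.
The GA is real-coded with tournament selection, blend crossover, bounded
Gaussian mutation and elitism, and stops after a configurable stagnation
window, echoing the optimize-until-no-change convention of resistance-
surface studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .model_engine import (MLPEStructure, dredge, fit_mlpe, lrt,
                           average_and_importance, rank_models, standardize)
from .raster import RasterGrid
from .relatedness import RelatednessMatrix
from .resistance import (DistanceMatrix, categorical_surface, commute_distance,
                         null_ibd_surface, transform_continuous)

__all__ = ["GAConfig", "OptimizationRun", "optimize_surface",
           "convergence_check", "compare_gene_flow_models", "mlpe_from_distance"]

_CONT_VARIANTS = ("forward", "reverse", "inverse", "inverse_reverse")


@dataclass
class GAConfig:
    """Real-coded GA settings and parameter bounds."""

    population: int = 50
    stagnation: int = 25          # generations without >= min_improvement
    min_improvement: float = 0.01  # AIC units
    max_generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.3
    mutation_scale: float = 0.10   # SD as fraction of each gene's range
    elitism: int = 2
    tournament: int = 3
    class_bounds: tuple = (1.0, 2500.0)
    shape_bounds: tuple = (0.05, 10.0)
    maximum_bounds: tuple = (1.5, 2500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 10:
            raise ValueError("population must be >= 10")
        for b in (self.class_bounds, self.shape_bounds, self.maximum_bounds):
            if not np.all(np.isfinite(b)):
                raise ValueError("parameter bounds must be finite")


@dataclass
class OptimizationRun:
    """Result of one GA run: best parameters and objective trajectory."""

    surface_kind: str
    layer_name: str
    best_params: dict
    trajectory: list
    final_objective: float
    seed: int
    n_evaluations: int
    best_distance: DistanceMatrix | None = None
    ga_config: GAConfig | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.trajectory)
        if len(t) and np.any(np.diff(t) > 1e-9):
            raise ValueError("best-objective trajectory must be non-increasing")


def _center_distance(matrix: np.ndarray) -> np.ndarray:
    """Double-center a distance matrix (Gower projection, -H D H shape).

    The relatedness response is itself a centered similarity matrix (allele
    frequencies are estimated from the sample), so the matching predictor
    geometry is the centered distance kernel; without this projection the
    additive row pattern of a raw distance matrix leaks into the residual
    and spuriously rewards surfaces that mimic sample eccentricity.
    """
    n = matrix.shape[0]
    H = np.eye(n) - 1.0 / n
    return H @ matrix @ H


def mlpe_from_distance(rel: RelatednessMatrix, dist: DistanceMatrix,
                       structure: MLPEStructure | None = None,
                       extra_params: int | None = None,
                       model_name: str = "", center: bool = True):
    """Univariate MLPE of relatedness on a standardized distance predictor.

    By default the distance matrix is double-centered before
    standardization (see :func:`_center_distance`).
    """
    n = rel.n
    if dist.n != n:
        raise ValueError("distance and relatedness cover different samples")
    iu = np.triu_indices(n, 1)
    M = _center_distance(dist.matrix) if center else dist.matrix
    tbl = pd.DataFrame({"id1": iu[0], "id2": iu[1],
                        "relatedness": rel.values[iu],
                        "dist": standardize(M[iu])})
    if extra_params is None:
        extra_params = int(dist.provenance.get("n_free_params", 0))
    return fit_mlpe(tbl, "relatedness", ["dist"], structure=structure,
                    extra_params=extra_params, model_name=model_name, n_eff=n)


def _decode(kind: str, genes: np.ndarray, layer: RasterGrid,
            class_codes: list, ga: GAConfig):
    """Genes -> resistance surface (and a readable parameter dict)."""
    if kind == "categorical":
        values = {c: float(10.0 ** g) for c, g in zip(class_codes, genes)}
        surface = categorical_surface(layer, values)
        return surface, {"class_values": values}
    shape = float(10.0 ** genes[0])
    maximum = float(10.0 ** genes[1])
    variant = _CONT_VARIANTS[int(np.clip(genes[2], 0, 3.999))]
    surface = transform_continuous(layer, family=kind, variant=variant,
                                   shape=shape, maximum=maximum)
    return surface, {"shape": shape, "maximum": maximum, "variant": variant}


def optimize_surface(rel: RelatednessMatrix, layer: RasterGrid,
                     surface_kind: str, ga: GAConfig | None = None,
                     coords: np.ndarray | None = None,
                     neighborhood: int = 8) -> OptimizationRun:
    """Optimize resistance-surface parameters by a real-coded GA.

    ``surface_kind`` is "categorical" (one value per land-cover class,
    searched on a log10 scale) or "monomolecular"/"ricker" (shape, maximum
    and transformation variant).  Candidates whose graph is disconnected
    across the samples are penalized with an infinite objective.
    """
    ga = ga or GAConfig()
    if coords is None:
        raise ValueError("sample coordinates are required")
    coords = np.asarray(coords, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence((ga.seed, 31)))
    n = rel.n
    iu = np.triu_indices(n, 1)
    structure = MLPEStructure(np.column_stack(iu))

    if surface_kind == "categorical":
        class_codes = sorted(int(c) for c in np.unique(
            layer.data[layer.data != layer.nodata]))
        n_genes = len(class_codes)
        lo = np.full(n_genes, np.log10(ga.class_bounds[0]))
        hi = np.full(n_genes, np.log10(ga.class_bounds[1]))
    elif surface_kind in ("monomolecular", "ricker"):
        class_codes = []
        lo = np.array([np.log10(ga.shape_bounds[0]),
                       np.log10(ga.maximum_bounds[0]), 0.0])
        hi = np.array([np.log10(ga.shape_bounds[1]),
                       np.log10(ga.maximum_bounds[1]), 3.999])
        n_genes = 3
    else:
        raise ValueError(f"unknown surface kind {surface_kind!r}")

    n_evals = 0

    def evaluate(genes) -> float:
        nonlocal n_evals
        n_evals += 1
        try:
            surface, _ = _decode(surface_kind, genes, layer, class_codes, ga)
            dist = commute_distance(surface, coords, neighborhood=neighborhood)
            fit = mlpe_from_distance(rel, dist, structure=structure,
                                     extra_params=surface.n_free_params)
            return float(fit.aicc)
        except (ValueError, np.linalg.LinAlgError):
            return np.inf

    pop = rng.uniform(lo, hi, size=(ga.population, n_genes))
    fitness = np.array([evaluate(ind) for ind in pop])
    best_idx = int(np.argmin(fitness))
    best_genes, best_fit = pop[best_idx].copy(), float(fitness[best_idx])
    trajectory = [best_fit]
    stagnant = 0
    for _gen in range(ga.max_generations):
        order = np.argsort(fitness)
        elite = pop[order[:ga.elitism]].copy()
        children = [e for e in elite]
        while len(children) < ga.population:
            def pick():
                cand = rng.integers(0, ga.population, ga.tournament)
                return pop[cand[np.argmin(fitness[cand])]]
            p1, p2 = pick(), pick()
            if rng.random() < ga.crossover_rate:
                alpha = rng.uniform(-0.5, 1.5, n_genes)
                child = alpha * p1 + (1 - alpha) * p2
            else:
                child = p1.copy()
            mut = rng.random(n_genes) < ga.mutation_rate
            child = child + mut * rng.normal(0, ga.mutation_scale * (hi - lo),
                                             n_genes)
            children.append(np.clip(child, lo, hi))
        pop = np.array(children[:ga.population])
        fitness = np.array([evaluate(ind) for ind in pop])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_fit - 1e-12:
            improved = best_fit - fitness[gen_best]
            best_fit = float(fitness[gen_best])
            best_genes = pop[gen_best].copy()
            stagnant = 0 if improved >= ga.min_improvement else stagnant + 1
        else:
            stagnant += 1
        trajectory.append(best_fit)
        if stagnant >= ga.stagnation:
            break
    surface, params = _decode(surface_kind, best_genes, layer, class_codes, ga)
    dist = commute_distance(surface, coords, neighborhood=neighborhood)
    return OptimizationRun(surface_kind=surface_kind, layer_name=layer.name,
                           best_params=params, trajectory=trajectory,
                           final_objective=best_fit, seed=ga.seed,
                           n_evaluations=n_evals, best_distance=dist,
                           ga_config=ga)


@dataclass
class ConvergenceReport:
    cv_objective: float
    agreements: list
    median_agreement: float
    passed: bool
    notes: dict = field(default_factory=dict)


def convergence_check(runs: list[OptimizationRun], cv_max: float = 0.05,
                      agreement_min: float = 0.8,
                      layer: RasterGrid | None = None) -> ConvergenceReport:
    """Agreement of independent optimization runs on one surface.

    Reports the coefficient of variation of final objectives and the
    pairwise Spearman agreement of per-class resistance values
    (categorical) or of cellwise surface values (continuous, requires
    ``layer``), with a pass flag at the given thresholds.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    kinds = {r.surface_kind for r in runs}
    layers = {r.layer_name for r in runs}
    if len(kinds) > 1 or len(layers) > 1:
        raise ValueError("runs come from different layers or surface kinds")
    finals = np.array([r.final_objective for r in runs])
    cv = float(finals.std() / abs(finals.mean())) if finals.mean() != 0 else np.inf
    kind = kinds.pop()
    vectors = []
    if kind == "categorical":
        codes = sorted(runs[0].best_params["class_values"])
        for r in runs:
            vectors.append([r.best_params["class_values"][c] for c in codes])
    else:
        if layer is None:
            raise ValueError("continuous agreement needs the source layer")
        for r in runs:
            s = transform_continuous(layer, family=kind,
                                     variant=r.best_params["variant"],
                                     shape=r.best_params["shape"],
                                     maximum=r.best_params["maximum"])
            vectors.append(s.values[np.isfinite(s.values)])
    agreements = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            rho = spearmanr(vectors[i], vectors[j]).statistic
            agreements.append(1.0 if np.isnan(rho) else float(rho))
    med = float(np.median(agreements))
    return ConvergenceReport(cv_objective=cv, agreements=agreements,
                             median_agreement=med,
                             passed=(cv <= cv_max and med >= agreement_min),
                             notes={"final_objectives": finals.tolist()})


def compare_gene_flow_models(landcover_distances: dict,
                             other_distances: dict,
                             rel: RelatednessMatrix,
                             ibd_distance: DistanceMatrix,
                             assignments=None,
                             collinearity_r: float = 0.6) -> dict:
    """Two-stage gene-flow model selection with the IBD-parsimony rule.

    Stage 1 ranks univariate MLPE models over the per-year land-cover
    distances plus geographic (IBD) distance; whenever the IBD model sits
    in the plausible set (dAIC <= 2), isolation by distance is recorded as
    the most parsimonious gene-flow model.  Stage 2 runs an all-subsets
    search over the stage-1 land-cover winner plus all other optimized
    surfaces (collinearity screened at |r| < ``collinearity_r``), and
    reports LRTs, variable importance and model-averaged coefficients.

    ``assignments`` (optional hard cluster labels) adds a same/different-
    cluster random intercept to every MLPE fit.
    """
    n = rel.n
    for name, d in {**landcover_distances, **other_distances,
                    "ibd": ibd_distance}.items():
        if d.n != n:
            raise ValueError(f"distance {name!r} covers {d.n} != {n} samples")
    iu = np.triu_indices(n, 1)
    structure = MLPEStructure(np.column_stack(iu))
    tbl = pd.DataFrame({"id1": iu[0], "id2": iu[1],
                        "relatedness": rel.values[iu]})
    extra_group = None
    if assignments is not None:
        a = np.asarray(assignments)
        tbl["same_cluster"] = (a[iu[0]] == a[iu[1]]).astype(int)
        extra_group = "same_cluster"
    all_d = {"ibd": ibd_distance, **landcover_distances, **other_distances}
    for name, d in all_d.items():
        tbl[name] = standardize(_center_distance(d.matrix)[iu])

    def fit_one(data, response, predictors, model_name="", extra_override=None):
        extra = (extra_override if extra_override is not None
                 else sum(int(all_d[p].provenance.get("n_free_params", 0))
                          for p in predictors))
        return fit_mlpe(data, response, predictors, structure=structure,
                        extra_group=extra_group, extra_params=extra,
                        model_name=model_name, n_eff=n)

    stage1_names = ["ibd"] + list(landcover_distances)
    stage1_fits = [fit_one(tbl, "relatedness", [nm], model_name=nm)
                   for nm in stage1_names]
    stage1 = rank_models(stage1_fits, criterion="aicc")
    best1 = stage1.best_set["model"].tolist()
    ibd_parsimonious = "ibd" in best1
    lc_winner = next((m for m in stage1.table["model"] if m != "ibd"), None)

    stage2_predictors = ([] if lc_winner is None else [lc_winner]) \
        + list(other_distances)
    stage2 = None
    lrt_rows = []
    averaging = None
    if stage2_predictors:
        stage2 = dredge(tbl, "relatedness", stage2_predictors, fit_one,
                        collinearity_r=collinearity_r, criterion="aicc")
        best_fit = stage2.best_fit
        best_terms = [t for t in best_fit.names if t != "(Intercept)"]
        full_extra = best_fit.n_params - (len(best_terms) + 1) - 2 \
            - (1 if extra_group else 0)
        for term in best_terms:
            reduced_terms = [t for t in best_terms if t != term]
            # keep the surface-parameter penalty of the full model so the
            # test df is exactly the dropped coefficient
            reduced = fit_one(tbl, "relatedness", reduced_terms,
                              model_name=" + ".join(reduced_terms) or "(null)",
                              extra_override=full_extra)
            D, p, df = lrt(best_fit, reduced)
            lrt_rows.append({"term": term, "D": D, "p": p, "df": df})
        averaging = average_and_importance(stage2)
    return {
        "stage1": stage1,
        "ibd_parsimonious": ibd_parsimonious,
        "landcover_winner": lc_winner,
        "stage2": stage2,
        "lrt": pd.DataFrame(lrt_rows),
        "averaging": averaging,
    }
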