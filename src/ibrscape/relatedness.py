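"""Pairwise relatedness, individual heterozygosity/inbreeding, and the
spatial autocorrelation correlogram.

The pairwise statistic is the allele-frequency-standardized relatedness of
Yang et al. (the GCTA/GRM estimator): for individuals j != k,

    A_jk = mean_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

averaged over loci where both calls are present, with p_i estimated from
the full sample; the diagonal uses the bias-corrected own-term
1 + mean_i (x^2 - (1 + 2p) x + 2 p^2) / (2pq).  Relatedness is the
response variable for every gene-flow model downstream.

Fine-scale structure is summarized by a LOESS fit of pairwise relatedness
against pairwise distance, with a null envelope from joint row/column
permutations of the relatedness matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "RelatednessMatrix", "Correlogram", "yang_relatedness",
    "individual_het_inbreeding", "loess_fit", "relatedness_correlogram",
    "pair_table",
]


@dataclass
class RelatednessMatrix:
    """n x n Yang relatedness values with per-pair locus counts."""

    values: np.ndarray
    n_loci_used: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(np.nan_to_num(self.values),
                           np.nan_to_num(self.values.T), atol=1e-10):
            raise ValueError("relatedness matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def to_long(self) -> pd.DataFrame:
        iu = np.triu_indices(self.n, 1)
        ids = self.sample_ids or list(range(self.n))
        return pd.DataFrame({
            "id1": [ids[i] for i in iu[0]],
            "id2": [ids[j] for j in iu[1]],
            "relatedness": self.values[iu],
            "n_loci": self.n_loci_used[iu],
        })


def yang_relatedness(geno: GenotypeTable) -> RelatednessMatrix:
    """Yang (GCTA) pairwise relatedness with missing-aware averaging.

    Monomorphic loci (p in {0, 1}) are excluded; pairs sharing no usable
    locus get NaN.  Allele frequencies come from the full sample.
    """
    if geno.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    X = geno.dosages_float()
    p = geno.allele_freq()
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all loci are monomorphic")
    X = X[:, poly]
    p = p[poly]
    denom = 2.0 * p * (1.0 - p)
    obs = ~np.isnan(X)
    Z = np.where(obs, (X - 2 * p) / np.sqrt(denom), 0.0)
    counts = obs.astype(float) @ obs.T.astype(float)
    cross = Z @ Z.T
    with np.errstate(invalid="ignore", divide="ignore"):
        A = cross / counts
    # diagonal: 1 + mean (x^2 - (1+2p)x + 2p^2) / 2pq
    own = np.where(obs, (X ** 2 - (1 + 2 * p) * X + 2 * p ** 2) / denom, 0.0)
    n_own = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        np.fill_diagonal(A, 1.0 + own.sum(axis=1) / n_own)
        np.fill_diagonal(counts, n_own)
    return RelatednessMatrix(values=A, n_loci_used=counts.astype(int),
                             sample_ids=list(geno.sample_ids))


def individual_het_inbreeding(geno: GenotypeTable) -> pd.DataFrame:
    """Observed heterozygosity H and method-of-moments inbreeding f.

    Per individual, over non-missing polymorphic loci: O = observed
    homozygote count, E = sum_i [1 - 2 p_i q_i 2n_i/(2n_i - 1)] the expected
    homozygote count under HWE (n_i = calls at locus i), N = usable loci;
    then f = (O - E)/(N - E) and H = 1 - O/N (the output of the usual
    per-individual het summary).  Individuals with no usable loci are
    returned with NaN, never dropped.
    """
    if geno.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    X = geno.dosages_float()
    p = geno.allele_freq()
    nn = geno.call_counts().astype(float)
    poly = (p > 0) & (p < 1)
    X = X[:, poly]
    p = p[poly]
    nn = nn[poly]
    e_hom_locus = 1.0 - 2.0 * p * (1 - p) * (2 * nn) / np.maximum(2 * nn - 1, 1)
    obs = ~np.isnan(X)
    hom = (X == 0) | (X == 2)
    O = np.where(obs, hom, 0).sum(axis=1).astype(float)
    N = obs.sum(axis=1).astype(float)
    E = obs @ e_hom_locus
    with np.errstate(invalid="ignore", divide="ignore"):
        H = 1.0 - O / N
        f = (O - E) / (N - E)
    H = np.where(N > 0, H, np.nan)
    f = np.where(N > 0, f, np.nan)
    return pd.DataFrame({"id": geno.sample_ids, "H": H, "f": f,
                         "n_sites": N.astype(int)})


def loess_fit(x: np.ndarray, y: np.ndarray, span: float = 0.75,
              grid: np.ndarray | None = None,
              flag_extrapolation: bool = True) -> np.ndarray:
    """Local linear regression with tricube weights (LOESS, degree 1).

    Each grid point is fitted by weighted least squares over its
    ceil(span * n) nearest data points, weighted by the tricube kernel of
    scaled distance.  Vectorized over the grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 points")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    grid = np.asarray(grid, dtype=float)
    if flag_extrapolation and (grid.min() < x.min() - 1e-12
                               or grid.max() > x.max() + 1e-12):
        raise ValueError("grid extends beyond the data range (extrapolation)")
    n = len(x)
    q = int(np.ceil(span * n))
    d = np.abs(grid[:, None] - x[None, :])            # (g, n)
    h = np.sort(d, axis=1)[:, q - 1]                  # span-th NN distance
    h = np.maximum(h, 1e-300)
    u = np.clip(d / h[:, None], 0.0, 1.0)
    w = (1.0 - u ** 3) ** 3
    # weighted linear fit per grid point, closed form
    xc = x[None, :] - grid[:, None]
    sw = w.sum(axis=1)
    swx = (w * xc).sum(axis=1)
    swx2 = (w * xc * xc).sum(axis=1)
    swy = (w * y).sum(axis=1)
    swxy = (w * xc * y).sum(axis=1)
    det = sw * swx2 - swx ** 2
    pred = np.empty(len(grid))
    ok = det > 1e-12 * np.maximum(sw * swx2, 1e-300)
    pred[ok] = (swx2[ok] * swy[ok] - swx[ok] * swxy[ok]) / det[ok]
    pred[~ok] = swy[~ok] / sw[~ok]                    # degenerate: local mean
    return pred


@dataclass
class Correlogram:
    """Observed LOESS curve and pointwise permutation envelope."""

    grid: np.ndarray
    observed: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    span: float
    n_perm: int
    seed: int
    warnings: list = field(default_factory=list)

    def significant(self) -> np.ndarray:
        """Grid points where the observed curve exits the null envelope."""
        return (self.observed < self.lower) | (self.observed > self.upper)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": self.grid, "observed": self.observed,
                             "lower": self.lower, "upper": self.upper,
                             "significant": self.significant()})


def relatedness_correlogram(rel: RelatednessMatrix, coords: np.ndarray,
                            n_perm: int = 999, span: float = 0.75,
                            seed: int = 0, n_grid: int = 50,
                            grid_quantiles: tuple = (0.01, 0.99)) -> Correlogram:
    """Spatial autocorrelation of relatedness with a permutation envelope.

    The observed curve is the LOESS of pairwise relatedness against pairwise
    geographic distance on a grid spanning the 1st-99th percentile of
    distances.  The null permutes row and column indices of the relatedness
    matrix jointly (preserving symmetry and the value multiset) and refits
    the LOESS on the same grid; the envelope is the pointwise 2.5 and 97.5
    percentile of the permuted curves.
    """
    coords = np.asarray(coords, dtype=float)
    n = rel.n
    if coords.shape[0] != n:
        raise ValueError("coords must match relatedness matrix order")
    warnings_list = []
    if n_perm < 99:
        warnings_list.append(f"n_perm={n_perm} < 99: envelope is unreliable")
    iu = np.triu_indices(n, 1)
    dist = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))[iu]
    vals = rel.values
    y = vals[iu]
    qlo, qhi = np.quantile(dist, grid_quantiles)
    grid = np.linspace(qlo, qhi, n_grid)
    observed = loess_fit(dist, y, span=span, grid=grid)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 29)))
    null = np.empty((n_perm, n_grid))
    for b in range(n_perm):
        perm = rng.permutation(n)
        yp = vals[np.ix_(perm, perm)][iu]
        null[b] = loess_fit(dist, yp, span=span, grid=grid)
    lower, upper = np.percentile(null, [2.5, 97.5], axis=0)
    return Correlogram(grid=grid, observed=observed, lower=lower, upper=upper,
                       span=span, n_perm=n_perm, seed=seed,
                       warnings=warnings_list)


def pair_table(rel: RelatednessMatrix, coords: np.ndarray | None = None,
               assignments: np.ndarray | None = None) -> pd.DataFrame:
    """Long-format pair table for MLPE modelling.

    Columns: integer indices ``id1``/``id2``, ``relatedness``, optionally
    ``geo_distance`` and a ``same_cluster`` factor.
    """
    n = rel.n
    iu = np.triu_indices(n, 1)
    df = pd.DataFrame({"id1": iu[0], "id2": iu[1],
                       "relatedness": rel.values[iu]})
    if coords is not None:
        coords = np.asarray(coords, dtype=float)
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        df["geo_distance"] = d[iu]
    if assignments is not None:
        a = np.asarray(assignments)
        df["same_cluster"] = (a[iu[0]] == a[iu[1]]).astype(int)
    return df
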