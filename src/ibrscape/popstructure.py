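"""Population structure: ancestry estimation, choice of K, clustering,
and per-cluster diversity summaries.

Ancestry is estimated by regularized nonnegative factorization of one-hot
encoded genotypes (the sparse-NMF scheme behind admixture-style programs):
X ~ Q G_onehot, with Q the individuals-by-K ancestry proportions (rows on
the probability simplex) and G the per-cluster genotype-state frequencies.
The number of clusters is chosen by masked-entry cross-validation, and an
independent k-means/BIC clustering of principal components provides the
complementary assignment the field's two-method convention calls for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "AncestryModel", "ClusterSummary", "estimate_ancestry", "choose_k",
    "pc_kmeans_bic", "cluster_diversity", "hard_assignments",
]


@dataclass
class AncestryModel:
    """Ancestry coefficients Q, cluster allele frequencies G, and fit info."""

    Q: np.ndarray            # individuals x K, rows sum to 1
    G: np.ndarray            # K x loci alternate-allele frequencies
    K: int
    alpha: float
    objective: float
    objective_path: list = field(default_factory=list)
    cv_error: float | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")
        if np.any((self.Q < -1e-9) | (self.Q > 1 + 1e-9)):
            raise ValueError("Q entries must be in [0, 1]")

    def hard_clusters(self) -> np.ndarray:
        return self.Q.argmax(axis=1)


def hard_assignments(model: AncestryModel) -> np.ndarray:
    """Map individuals to clusters by maximum ancestry coefficient."""
    return model.hard_clusters()


def ancestry_from_labels(geno: GenotypeTable, labels) -> AncestryModel:
    """Ancestry model from hard cluster labels (one-hot Q, empirical G).

    Useful when structure was assessed elsewhere: the differentiation
    outlier scan takes cluster allele frequencies from any ancestry model.
    """
    labels = np.asarray(labels)
    levels = list(pd.unique(labels))
    K = len(levels)
    n = geno.n_individuals
    Q = np.zeros((n, K))
    G = np.zeros((K, geno.n_loci))
    X = geno.dosages_float()
    for k, lv in enumerate(levels):
        mask = labels == lv
        Q[mask, k] = 1.0
        with np.errstate(invalid="ignore"):
            G[k] = np.nanmean(X[mask], axis=0) / 2.0
    G = np.nan_to_num(G, nan=0.5)
    return AncestryModel(Q=Q, G=G, K=K, alpha=0.0, objective=0.0)


def _one_hot(geno: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """One-hot encode genotypes; missing triplets imputed with locus means.

    Returns (X of shape (n, 3L), missing mask of shape (n, L)).
    """
    d = geno.dosages
    n, L = d.shape
    X = np.zeros((n, 3 * L))
    miss = d == MISSING
    for g in (0, 1, 2):
        X[:, g::3] = (d == g).astype(float)
    counts = X.reshape(n, L, 3).sum(axis=0)
    nn = np.maximum(counts.sum(axis=1, keepdims=True), 1)
    freqs = counts / nn
    Xr = X.reshape(n, L, 3)
    Xr[miss] = freqs[np.where(miss)[1]]
    return Xr.reshape(n, 3 * L), miss


def _project_simplex(Q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = Q.shape
    u = -np.sort(-Q, axis=1)
    css = np.cumsum(u, axis=1)
    rho = np.sum(u + (1.0 - css) / np.arange(1, k + 1) > 0, axis=1)
    theta = (css[np.arange(n), rho - 1] - 1.0) / rho
    return np.maximum(Q - theta[:, None], 0.0)


def _g_from_onehot(Gh: np.ndarray) -> np.ndarray:
    """Cluster alternate-allele frequencies from genotype-state frequencies."""
    K = Gh.shape[0]
    L = Gh.shape[1] // 3
    Gr = Gh.reshape(K, L, 3)
    return np.clip(0.5 * Gr[:, :, 1] + Gr[:, :, 2], 0.0, 1.0)


def estimate_ancestry(geno: GenotypeTable, K: int, alpha: float = 1.0,
                      seed: int = 0, restarts: int = 5,
                      max_iter: int = 60, tol: float = 1e-6) -> AncestryModel:
    """Regularized alternating least squares on one-hot genotypes.

    Each sweep solves G given Q (genotype-state frequencies clipped to
    [0, 1] and renormalized per locus), then Q given G with a ridge penalty
    ``alpha`` and a simplex projection of the rows.  A sweep is accepted
    only if the penalized objective decreases, which makes the objective
    path monotone; the best of ``restarts`` random initializations wins.
    K = 1 returns a single all-ones column.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > geno.n_individuals:
        raise ValueError(f"K={K} exceeds {geno.n_individuals} individuals")
    X, _ = _one_hot(geno)
    n, _ = X.shape
    L = geno.n_loci
    if K == 1:
        Q = np.ones((n, 1))
        Gh = X.mean(axis=0, keepdims=True)
        obj = float(((X - Q @ Gh) ** 2).sum())
        return AncestryModel(Q=Q, G=_g_from_onehot(Gh), K=1, alpha=alpha,
                             objective=obj, objective_path=[obj])

    def objective(Q, Gh):
        return float(((X - Q @ Gh) ** 2).sum() + alpha * (Q ** 2).sum())

    def solve_G(Q):
        QtQ = Q.T @ Q + 1e-9 * np.eye(K)
        Gh = np.linalg.solve(QtQ, Q.T @ X)
        Gh = np.clip(Gh, 0.0, 1.0)
        Gr = Gh.reshape(K, L, 3)
        s = np.maximum(Gr.sum(axis=2, keepdims=True), 1e-12)
        return (Gr / s).reshape(K, 3 * L)

    def solve_Q(Gh):
        GGt = Gh @ Gh.T + alpha * np.eye(K)
        Q = np.linalg.solve(GGt, Gh @ X.T).T
        return _project_simplex(Q)

    ss = np.random.SeedSequence((seed, K))
    best = None
    for child in ss.spawn(restarts):
        rng = np.random.default_rng(child)
        Q = rng.dirichlet(np.ones(K), size=n)
        Gh = solve_G(Q)
        obj = objective(Q, Gh)
        path = [obj]
        for _ in range(max_iter):
            Q_new = solve_Q(Gh)
            Gh_new = solve_G(Q_new)
            obj_new = objective(Q_new, Gh_new)
            if obj_new > obj - tol * max(abs(obj), 1.0):
                if obj_new < obj:
                    Q, Gh, obj = Q_new, Gh_new, obj_new
                    path.append(obj)
                break
            Q, Gh, obj = Q_new, Gh_new, obj_new
            path.append(obj)
        if best is None or obj < best[2]:
            best = (Q, Gh, obj, path)
    Q, Gh, obj, path = best
    # guard against empty clusters collapsing row sums
    Q = np.clip(Q, 0.0, 1.0)
    Q = Q / Q.sum(axis=1, keepdims=True)
    return AncestryModel(Q=Q, G=_g_from_onehot(Gh), K=K, alpha=alpha,
                         objective=obj, objective_path=path)


def predict_dosage(model: AncestryModel) -> np.ndarray:
    """Expected dosage per individual and locus: 2 * Q p."""
    return 2.0 * (model.Q @ model.G)


def choose_k(geno: GenotypeTable, k_range=(1, 10), holdout_frac: float = 0.10,
             n_folds: int = 3, seed: int = 0, alpha: float = 1.0,
             restarts: int = 2) -> tuple[int, pd.DataFrame]:
    """Choose K by masked-entry cross-validation.

    For each fold a random fraction of the non-missing genotype entries is
    hidden (set missing), the ancestry model is fitted to the masked data,
    and squared error of the imputed dosage 2 Q p is scored on the hidden
    entries.  The best K minimizes the mean error; ties break toward the
    smaller K.  Returns (best_k, error curve DataFrame).
    """
    lo, hi = int(k_range[0]), int(k_range[-1])
    hi = min(hi, geno.n_individuals)
    if lo < 1:
        raise ValueError("k_range must start at >= 1")
    obs = np.argwhere(geno.dosages != MISSING)
    if holdout_frac >= 0.5:
        raise ValueError("holdout fraction leaves < 50% of entries per locus")
    ss = np.random.SeedSequence((seed, 17))
    rows = []
    for fold, child in enumerate(ss.spawn(n_folds)):
        rng = np.random.default_rng(child)
        n_hide = int(np.ceil(holdout_frac * len(obs)))
        hide = obs[rng.choice(len(obs), size=n_hide, replace=False)]
        masked = geno.dosages.copy()
        truth = masked[hide[:, 0], hide[:, 1]].astype(float)
        masked[hide[:, 0], hide[:, 1]] = MISSING
        masked_geno = GenotypeTable(masked, geno.loci, list(geno.sample_ids))
        for k in range(lo, hi + 1):
            model = estimate_ancestry(masked_geno, k, alpha=alpha,
                                      seed=seed + fold, restarts=restarts)
            pred = predict_dosage(model)[hide[:, 0], hide[:, 1]]
            err = float(np.mean((pred - truth) ** 2))
            rows.append({"fold": fold, "K": k, "error": err})
    curve = (pd.DataFrame(rows).groupby("K", as_index=False)["error"].mean())
    best_err = curve["error"].min()
    best_k = int(curve.loc[curve["error"] <= best_err + 1e-12, "K"].min())
    return best_k, curve


def pc_kmeans_bic(geno: GenotypeTable, k_range=(1, 10), n_pcs: int | None = None,
                  seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """Successive k-means on principal components, scored by BIC.

    Dosages are mean-imputed, centered and scaled, projected on the top
    principal components (default: the smallest number explaining >= 90%
    of variance); BIC(k) = n ln(WSS_k / n) + k ln(n).  Returns the
    assignment at the BIC-optimal k and the BIC curve.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = geno.dosages_float()
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = mu[inds[1]]
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / X[:, keep].std(axis=0)
    n = Xs.shape[0]
    n_comp = min(n - 1, Xs.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(Xs)
    if n_pcs is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pcs = int(np.searchsorted(cum, 0.90) + 1)
    n_pcs = min(n_pcs, scores.shape[1])
    Z = scores[:, :n_pcs]
    rows, labels_by_k = [], {}
    lo, hi = int(k_range[0]), int(k_range[-1])
    for k in range(lo, hi + 1):
        if k > n:
            rows.append({"K": k, "WSS": np.nan, "BIC": np.nan,
                         "note": "skipped: k > n"})
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
        wss = float(km.inertia_)
        bic = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
        rows.append({"K": k, "WSS": wss, "BIC": bic, "note": ""})
        labels_by_k[k] = km.labels_
    curve = pd.DataFrame(rows)
    ok = curve.dropna(subset=["BIC"])
    best_k = int(ok.loc[ok["BIC"].idxmin(), "K"])
    return labels_by_k[best_k], curve


@dataclass
class ClusterSummary:
    """Per-cluster sample size, expected heterozygosity and inbreeding."""

    cluster: int
    n: int
    he: float
    he_ci: tuple
    f: float
    f_ci: tuple


def _cluster_he(dosages: np.ndarray) -> np.ndarray:
    """Unbiased per-locus expected heterozygosity 2pq * 2n/(2n-1)."""
    x = dosages.astype(float)
    x[dosages == MISSING] = np.nan
    nn = np.sum(~np.isnan(x), axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(x, axis=0) / 2.0
    he = 2.0 * p * (1 - p) * (2 * nn) / np.maximum(2 * nn - 1, 1)
    return np.where(nn > 0, he, np.nan)


def cluster_diversity(geno: GenotypeTable, assignments,
                      n_boot: int = 500, seed: int = 0) -> list[ClusterSummary]:
    """Per-cluster mean expected heterozygosity and mean inbreeding.

    H_E averages the unbiased per-locus heterozygosity over loci polymorphic
    within the cluster; F averages the per-individual method-of-moments
    inbreeding coefficient computed from within-cluster allele frequencies.
    95% CIs are percentile bootstraps over loci.
    """
    from .relatedness import individual_het_inbreeding

    assignments = np.asarray(assignments)
    if len(assignments) != geno.n_individuals:
        raise ValueError("one assignment per individual required")
    out = []
    ss = np.random.SeedSequence((seed, 23))
    for cl, child in zip(np.unique(assignments), ss.spawn(len(np.unique(assignments)))):
        rng = np.random.default_rng(child)
        members = np.flatnonzero(assignments == cl)
        if len(members) < 2:
            raise ValueError(f"cluster {cl} has fewer than 2 individuals")
        sub = geno.subset_individuals(members)
        he_loc = _cluster_he(sub.dosages)
        poly = (np.nan_to_num(he_loc) > 0)
        he_vals = he_loc[poly]
        he = float(he_vals.mean()) if he_vals.size else 0.0
        div = individual_het_inbreeding(sub)
        f_ind = div["f"].to_numpy()
        f = float(np.nanmean(f_ind)) if np.any(~np.isnan(f_ind)) else float("nan")
        # bootstrap over loci
        he_bs, f_bs = [], []
        poly_idx = np.flatnonzero(poly)
        for _ in range(n_boot):
            bs = rng.choice(sub.n_loci, size=sub.n_loci, replace=True)
            he_b = he_loc[bs]
            he_b = he_b[np.nan_to_num(he_b) > 0]
            he_bs.append(he_b.mean() if he_b.size else 0.0)
            div_b = individual_het_inbreeding(sub.subset_loci(bs))
            f_bs.append(np.nanmean(div_b["f"].to_numpy()))
        he_ci = tuple(np.percentile(he_bs, [2.5, 97.5])) if n_boot else (he, he)
        f_ci = tuple(np.percentile(f_bs, [2.5, 97.5])) if n_boot else (f, f)
        out.append(ClusterSummary(cluster=int(cl), n=len(members), he=he,
                                  he_ci=he_ci, f=f, f_ci=f_ci))
    return out
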