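"""Likelihood machinery for spatial and pairwise regression.

Three Gaussian model families share one marginal-likelihood core:

* :func:`fit_gls` — generalized least squares with a spatial correlation
  structure (linear, exponential, Gaussian, or spherical in distance) and
  optional per-group variance weights for heteroscedasticity;
* :func:`fit_lmm` — linear mixed models with one or two crossed
  random-intercept factors, fitted by profiled ML;
* :func:`fit_mlpe` — the maximum-likelihood-population-effects model for
  pairwise distance data, in which two rows (pairs) that share an individual
  are correlated with rho = sigma_u^2 / (2 sigma_u^2 + sigma_eps^2) < 0.5.

All fits profile beta and sigma^2 analytically and optimize the remaining
variance-ratio parameters numerically, under ML (REML likelihoods are not
comparable across fixed-effect structures, and every downstream comparison
is AIC-based).  Multimodel inference (AIC ranking, Akaike weights, the
delta-AIC <= 2 plausible set, likelihood-ratio tests, conditional model
averaging, variable importance, all-subsets search with a collinearity
screen) operates on the resulting :class:`FitResult` objects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, eigh

__all__ = [
    "FitResult", "ModelTable", "fit_gls", "fit_lmm", "fit_mlpe",
    "MLPEStructure", "rank_models", "lrt", "average_and_importance",
    "dredge", "standardize",
]

_Z95 = stats.norm.ppf(0.975)


def standardize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance rescaling (constant input maps to zeros)."""
    x = np.asarray(x, dtype=float)
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


@dataclass
class FitResult:
    """Fitted coefficients, variance parameters, log-likelihood and AIC."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    converged: bool = True
    method: str = "ML"
    cov_params: dict = field(default_factory=dict)
    model_name: str = ""
    Sigma: np.ndarray | None = None  # fitted marginal covariance (small n only)
    n_eff: int | None = None  # effective sample size for AICc (individuals)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def aicc(self) -> float:
        """Small-sample AIC; the effective sample size is ``n_eff`` when set
        (for pairwise data: the number of individuals, the convention of
        resistance-surface optimization tools), else ``n_obs``."""
        n = self.n_eff if self.n_eff is not None else self.n_obs
        k = self.n_params
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def ci_lower(self) -> np.ndarray:
        return self.coef - _Z95 * self.se

    @property
    def ci_upper(self) -> np.ndarray:
        return self.coef + _Z95 * self.se

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
        }, index=self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])


def _design(data: pd.DataFrame, predictors: list[str]) -> tuple[np.ndarray, list]:
    X = np.column_stack([np.ones(len(data))]
                        + [np.asarray(data[p], dtype=float) for p in predictors])
    return X, ["(Intercept)"] + list(predictors)


def _profile_mvn(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Profile beta and sigma^2 out of N(Xb, sigma^2 V); return key pieces.

    Returns (loglik, beta, sigma2, xtvix_inv) or None when V is not PD.
    """
    n = len(y)
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return None
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = cho_solve((c, low), X)
    Vi_y = cho_solve((c, low), y)
    xtvix = X.T @ Vi_X
    try:
        xtvix_inv = np.linalg.inv(xtvix)
    except np.linalg.LinAlgError:
        return None
    beta = xtvix_inv @ (X.T @ Vi_y)
    r = y - X @ beta
    rss = float(r @ cho_solve((c, low), r))
    if rss <= 0:
        rss = 1e-300
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, beta, sigma2, xtvix_inv


CORRELATION_FAMILIES = ("none", "linear", "exponential", "gaussian", "spherical")


def _correlation(d: np.ndarray, family: str, rng: float) -> np.ndarray:
    h = d / rng
    if family == "exponential":
        return np.exp(-h)
    if family == "gaussian":
        return np.exp(-h ** 2)
    if family == "spherical":
        c = 1.0 - 1.5 * h + 0.5 * h ** 3
        return np.where(h < 1.0, c, 0.0)
    if family == "linear":
        return np.maximum(0.0, 1.0 - h)
    raise ValueError(f"unknown correlation family {family!r}")


def fit_gls(data: pd.DataFrame, response: str, predictors: list[str],
            coords: np.ndarray | None = None, family: str = "none",
            weights_group: str | None = None, model_name: str = "",
            jitter: float = 1e-8) -> FitResult:
    """GLS with an optional spatial correlation structure.

    The marginal covariance is sigma^2 * W^{1/2} C(range) W^{1/2}, where C
    comes from ``family`` evaluated on pairwise Euclidean distances of
    ``coords`` and W holds per-group variance multipliers (reference group
    fixed at 1) when ``weights_group`` names a column of ``data``.  The
    range (and the log variance multipliers) are optimized by ML; beta and
    sigma^2 are profiled.  Wald standard errors.
    """
    y = np.asarray(data[response], dtype=float)
    X, names = _design(data, predictors)
    n = len(y)
    if family != "none":
        if coords is None:
            raise ValueError("coords required for a spatial correlation family")
        coords = np.asarray(coords, dtype=float)
        dmat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    groups = None
    if weights_group is not None:
        labels = np.asarray(data[weights_group])
        levels = list(pd.unique(labels))
        groups = [(labels == lv) for lv in levels[1:]]  # first level = reference

    def build_V(theta):
        V = np.eye(n)
        k = 0
        if family != "none":
            rng_par = np.exp(theta[0])
            V = _correlation(dmat, family, rng_par)
            np.fill_diagonal(V, 1.0)
            V = V + jitter * np.eye(n)
            k = 1
        if groups:
            w = np.ones(n)
            for g, mask in enumerate(groups):
                w[mask] = np.exp(theta[k + g])
            sw = np.sqrt(w)
            V = V * np.outer(sw, sw)
        return V

    n_theta = (1 if family != "none" else 0) + (len(groups) if groups else 0)
    if n_theta == 0:
        prof = _profile_mvn(y, X, np.eye(n))
        theta_hat = np.array([])
        converged = True
    else:
        if family != "none":
            off = dmat[np.triu_indices(n, 1)]
            med = np.median(off[off > 0]) if np.any(off > 0) else 1.0
        x0 = np.zeros(n_theta)
        if family != "none":
            x0[0] = np.log(med)

        def neg_ll(theta):
            prof = _profile_mvn(y, X, build_V(theta))
            return 1e10 if prof is None else -prof[0]

        res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8,
                                         "maxiter": 2000})
        theta_hat = res.x
        converged = bool(res.success)
        prof = _profile_mvn(y, X, build_V(theta_hat))
        if prof is None:
            raise RuntimeError("covariance not positive definite at optimum")
    ll, beta, sigma2, xtvix_inv = prof
    se = np.sqrt(np.maximum(np.diag(xtvix_inv) * sigma2 * n / max(n - X.shape[1], 1), 0))
    cov_params = {"sigma2": sigma2, "family": family}
    if family != "none":
        cov_params["range"] = float(np.exp(theta_hat[0]))
    if groups:
        k = 1 if family != "none" else 0
        cov_params["variance_weights"] = [1.0] + [float(np.exp(t)) for t in theta_hat[k:]]
    n_params = X.shape[1] + 1 + n_theta
    V = build_V(theta_hat) if n_theta else np.eye(n)
    return FitResult(names=names, coef=beta, se=se, loglik=ll,
                     n_params=n_params, n_obs=n, converged=converged,
                     cov_params=cov_params, model_name=model_name,
                     Sigma=sigma2 * V if n <= 500 else None)


def _indicator(labels) -> np.ndarray:
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    Z = np.zeros((len(labels), len(levels)))
    for k, lv in enumerate(levels):
        Z[labels == lv, k] = 1.0
    return Z


def fit_lmm(data: pd.DataFrame, response: str, predictors: list[str],
            groups: list[str], model_name: str = "") -> FitResult:
    """Random-intercept linear mixed model via profiled ML.

    ``groups`` names one or two columns of ``data`` defining crossed
    random-intercept factors.  The covariance is
    sigma^2 (I + sum_f gamma_f Z_f Z_f'); the variance ratios gamma_f are
    optimized on a log scale, beta and sigma^2 profiled.  A fit driven to
    the gamma -> 0 boundary is flagged singular but still returned.
    """
    y = np.asarray(data[response], dtype=float)
    X, names = _design(data, predictors)
    n = len(y)
    Zs = [_indicator(data[g]) for g in groups]
    for g, Z in zip(groups, Zs):
        if Z.shape[1] < 2:
            raise ValueError(f"random factor {g!r} needs >= 2 levels")
    ZZ = [Z @ Z.T for Z in Zs]

    def build_V(theta):
        V = np.eye(n)
        for t, M in zip(theta, ZZ):
            V = V + np.exp(t) * M
        return V

    def neg_ll(theta):
        prof = _profile_mvn(y, X, build_V(theta))
        return 1e10 if prof is None else -prof[0]

    x0 = np.zeros(len(Zs))
    res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-9,
                                     "maxiter": 4000})
    theta_hat = np.clip(res.x, -25, 25)
    prof = _profile_mvn(y, X, build_V(theta_hat))
    ll, beta, sigma2, xtvix_inv = prof
    se = np.sqrt(np.maximum(np.diag(xtvix_inv) * sigma2 * n / max(n - X.shape[1], 1), 0))
    gammas = np.exp(theta_hat)
    cov_params = {
        "sigma2_resid": sigma2,
        "group_variances": {g: float(sigma2 * gm) for g, gm in zip(groups, gammas)},
        "singular": bool(np.any(gammas < 1e-6)),
    }
    return FitResult(names=names, coef=beta, se=se, loglik=ll,
                     n_params=X.shape[1] + 1 + len(Zs), n_obs=n,
                     converged=bool(res.success), cov_params=cov_params,
                     model_name=model_name,
                     Sigma=sigma2 * build_V(theta_hat) if n <= 500 else None)


class MLPEStructure:
    """Cached spectral decomposition of the MLPE pair covariance.

    For rows indexed by unordered pairs (i, j) of individuals, A is the
    pair-by-individual incidence matrix (two ones per row) and the MLPE
    covariance is sigma^2 (I + gamma A A').  The eigendecomposition
    A A' = Q diag(lam) Q' depends only on the pair structure, so one
    decomposition serves every likelihood evaluation and every response —
    the resistance-surface optimizer exploits this heavily.
    """

    def __init__(self, pairs: np.ndarray, n_individuals: int | None = None):
        pairs = np.asarray(pairs, dtype=int)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("pairs must be (n_pairs, 2) integer indices")
        key = {tuple(sorted(p)) for p in pairs}
        if len(key) != len(pairs):
            raise ValueError("duplicate pairs in MLPE table")
        if np.any(pairs[:, 0] == pairs[:, 1]):
            raise ValueError("self-pairs are not allowed")
        self.pairs = pairs
        m = int(pairs.max()) + 1 if n_individuals is None else n_individuals
        A = np.zeros((len(pairs), m))
        A[np.arange(len(pairs)), pairs[:, 0]] = 1.0
        A[np.arange(len(pairs)), pairs[:, 1]] = 1.0
        self.A = A
        lam, Q = eigh(A @ A.T)
        self.lam = np.maximum(lam, 0.0)
        self.Q = Q

    def rotate(self, v: np.ndarray) -> np.ndarray:
        return self.Q.T @ v


def fit_mlpe(pair_table: pd.DataFrame, response: str, predictors: list[str],
             id_cols: tuple[str, str] = ("id1", "id2"),
             extra_group: str | None = None,
             structure: MLPEStructure | None = None,
             model_name: str = "",
             extra_params: int = 0,
             n_eff: int | None = None) -> FitResult:
    """MLPE regression of a pairwise response on pairwise predictors.

    Each row of ``pair_table`` is an unordered pair of individuals
    (integer-coded in ``id_cols``).  The fitted correlation between two
    rows sharing one individual is rho = gamma / (2 gamma + 1) in (0, 0.5).
    ``extra_group`` optionally names a column defining an additional
    random-intercept factor (e.g. same- vs different-cluster pairs).
    ``extra_params`` is added to the parameter count in the AIC — used to
    charge optimized resistance surfaces for their free parameters.
    """
    y = np.asarray(pair_table[response], dtype=float)
    X, names = _design(pair_table, predictors)
    n = len(y)
    pairs = pair_table[list(id_cols)].to_numpy(dtype=int)
    if structure is None:
        structure = MLPEStructure(pairs)
    elif not np.array_equal(structure.pairs, pairs):
        raise ValueError("supplied MLPE structure does not match the pair table")

    if extra_group is None:
        lam = structure.lam
        yt = structure.rotate(y)
        Xt = structure.rotate(X)

        def neg_ll(log_gamma):
            g = np.exp(log_gamma)
            w = 1.0 + g * lam         # eigenvalues of V
            logdet = float(np.sum(np.log(w)))
            Wi = 1.0 / w
            xtvix = Xt.T @ (Wi[:, None] * Xt)
            try:
                xtvix_inv = np.linalg.inv(xtvix)
            except np.linalg.LinAlgError:
                return 1e10
            beta = xtvix_inv @ (Xt.T @ (Wi * yt))
            r = yt - Xt @ beta
            rss = float(r @ (Wi * r))
            sigma2 = max(rss / n, 1e-300)
            return 0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)

        res = optimize.minimize_scalar(neg_ll, bounds=(-12.0, 12.0),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        gamma = float(np.exp(res.x))
        w = 1.0 + gamma * lam
        Wi = 1.0 / w
        xtvix_inv = np.linalg.inv(Xt.T @ (Wi[:, None] * Xt))
        beta = xtvix_inv @ (Xt.T @ (Wi * yt))
        r = yt - Xt @ beta
        sigma2 = float(r @ (Wi * r)) / n
        ll = -float(neg_ll(res.x))
        V = None
        if n <= 1000:
            V = structure.Q @ (w[:, None] * structure.Q.T)
        n_theta = 1
        theta_extra = {}
        converged = True
    else:
        Zg = _indicator(pair_table[extra_group])
        ZZg = Zg @ Zg.T
        AA = structure.A @ structure.A.T

        def build_V(theta):
            return np.eye(n) + np.exp(theta[0]) * AA + np.exp(theta[1]) * ZZg

        def neg_ll2(theta):
            prof = _profile_mvn(y, X, build_V(theta))
            return 1e10 if prof is None else -prof[0]

        res = optimize.minimize(neg_ll2, np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-9,
                                         "maxiter": 3000})
        gamma = float(np.exp(res.x[0]))
        V = build_V(res.x)
        prof = _profile_mvn(y, X, V)
        ll, beta, sigma2, xtvix_inv = prof
        n_theta = 2
        theta_extra = {"extra_group_variance": float(sigma2 * np.exp(res.x[1]))}
        converged = bool(res.success)

    se = np.sqrt(np.maximum(np.diag(xtvix_inv) * sigma2 * n / max(n - X.shape[1], 1), 0))
    rho = gamma / (2.0 * gamma + 1.0)
    cov_params = {"sigma2": sigma2, "gamma": gamma, "rho": rho, **theta_extra}
    n_params = X.shape[1] + 1 + n_theta + extra_params
    return FitResult(names=names, coef=beta, se=se, loglik=ll,
                     n_params=n_params, n_obs=n, converged=converged,
                     cov_params=cov_params, model_name=model_name,
                     Sigma=sigma2 * V if V is not None and n <= 1000 else None,
                     n_eff=n_eff)


@dataclass
class ModelTable:
    """Ranked model set with Akaike weights and the plausible (dAIC<=2) set."""

    table: pd.DataFrame
    fits: list
    best_cutoff: float = 2.0

    @property
    def best_set(self) -> pd.DataFrame:
        return self.table[self.table["dAIC"] <= self.best_cutoff]

    @property
    def best_fit(self) -> FitResult:
        return self.fits[int(self.table.index[0])]

    def best_fits(self) -> list:
        return [self.fits[int(i)] for i in self.best_set.index]


def rank_models(fits: list[FitResult], best_cutoff: float = 2.0,
                criterion: str = "aic") -> ModelTable:
    """Information-criterion ranking: dAIC from the best model, Akaike
    weights summing to 1.  ``criterion`` is "aic" or "aicc" (the latter for
    pairwise resistance-surface models, charged for their surface
    parameters)."""
    if not fits:
        raise ValueError("no fits to rank")
    methods = {f.method for f in fits}
    if len(methods) > 1:
        raise ValueError(f"cannot rank fits with mixed estimation methods {methods}")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) > 1:
        raise ValueError("fits use different numbers of observations")
    aic = np.array([getattr(f, criterion) for f in fits])
    daic = aic - aic.min()
    w = np.exp(-0.5 * daic)
    w = w / w.sum()
    tbl = pd.DataFrame({
        "model": [f.model_name or f"model_{i}" for i, f in enumerate(fits)],
        "n_params": [f.n_params for f in fits],
        "logLik": [f.loglik for f in fits],
        "AIC": aic, "dAIC": daic, "wAIC": w,
    }).sort_values("AIC", kind="stable")
    return ModelTable(table=tbl, fits=list(fits), best_cutoff=best_cutoff)


def lrt(full: FitResult, reduced: FitResult) -> tuple[float, float, int]:
    """Likelihood-ratio test of nested ML fits: (D, p, df)."""
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("LRT requires ML fits")
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than reduced")
    D = 2.0 * (full.loglik - reduced.loglik)
    if D < -1e-6:
        raise ValueError("negative deviance: models not nested or fit failed")
    D = max(D, 0.0)
    return D, float(stats.chi2.sf(D, df)), df


def average_and_importance(table: ModelTable) -> dict:
    """Conditional model averaging and variable importance over the best set.

    Importance(v) = sum of renormalized Akaike weights of best-set models in
    which v appears.  The averaged coefficient for a term is the weight-
    normalized mean over best-set models containing it; its unconditional
    standard error combines within-model variance and between-model spread.
    """
    best = table.best_set
    idx = [int(i) for i in best.index]
    w = best["wAIC"].to_numpy()
    w = w / w.sum()
    fits = [table.fits[i] for i in idx]
    terms: list[str] = []
    for f in fits:
        for t in f.names:
            if t not in terms:
                terms.append(t)
    rows = {}
    importance = {}
    for t in terms:
        has = np.array([t in f.names for f in fits])
        importance[t] = float(w[has].sum())
        if not has.any():
            continue
        wt = w[has] / w[has].sum()
        b = np.array([f[t] for f, h in zip(fits, has) if h])
        s = np.array([f.se[f.names.index(t)] for f, h in zip(fits, has) if h])
        bbar = float(wt @ b)
        se_u = float(wt @ np.sqrt(s ** 2 + (b - bbar) ** 2))
        rows[t] = {"coef": bbar, "se": se_u,
                   "ci_lower": bbar - _Z95 * se_u, "ci_upper": bbar + _Z95 * se_u,
                   "importance": importance[t]}
    avg = pd.DataFrame(rows).T
    return {"averaged": avg, "importance": importance}


def enumerate_subsets(predictors: list[str], corr: pd.DataFrame,
                      collinearity_r: float = 0.6) -> list[tuple[str, ...]]:
    """All predictor subsets with no pair at |Pearson r| >= collinearity_r."""
    banned = set()
    for a, b in itertools.combinations(predictors, 2):
        if abs(corr.loc[a, b]) >= collinearity_r:
            banned.add(frozenset((a, b)))
    out = []
    for k in range(len(predictors) + 1):
        for sub in itertools.combinations(predictors, k):
            if not any(frozenset(p) <= set(sub) for p in banned):
                out.append(sub)
    return out


def dredge(data: pd.DataFrame, response: str, predictors: list[str],
           fit_fn, collinearity_r: float = 0.6,
           max_models: int = 4096, criterion: str = "aic") -> ModelTable:
    """All-subsets model selection with a collinearity screen.

    ``fit_fn(data, response, predictors, model_name)`` fits one candidate
    (the null model is the empty subset).  Subsets containing a predictor
    pair with |r| >= ``collinearity_r`` are skipped.
    """
    corr = data[predictors].corr() if predictors else pd.DataFrame()
    subsets = enumerate_subsets(list(predictors), corr, collinearity_r)
    if len(subsets) > max_models:
        raise ValueError(
            f"{len(subsets)} candidate models exceed the limit {max_models}; "
            "reduce the predictor set")
    fits = []
    for sub in subsets:
        name = " + ".join(sub) if sub else "(null)"
        fits.append(fit_fn(data, response, list(sub), model_name=name))
    return rank_models(fits, criterion=criterion)
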