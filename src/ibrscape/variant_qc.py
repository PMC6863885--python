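"""Neutral-and-independent locus pipeline: site filters, exact HWE test,
LD pruning, F_ST outlier scan with genomic-control calibration, and
Benjamini-Hochberg FDR control.

The default thresholds are the ones used throughout this kind of
reduced-representation dataset: loci are dropped when more than 30% of
calls are missing, site phred quality is <= 50, mean depth falls outside
30-240, minor-allele frequency is below 3%, every sample is heterozygous
(a collapsed-paralog signature), the exact Hardy-Weinberg test gives
P < 1e-4, or squared dosage correlation with a retained locus is >= 0.6.
Loci flagged by the differentiation outlier scan are removed last, leaving
a neutral, independent marker set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "FilterReport", "filter_sites", "hwe_exact_test", "hwe_filter",
    "ld_prune", "fst_outlier_scan", "bh_adjust", "run_qc",
]


@dataclass
class FilterReport:
    """Per-rule removal counts in application order, plus survivors."""

    n_input: int
    rules: list = field(default_factory=list)  # (rule, n_removed, removed_ids)
    surviving_ids: list = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def add(self, rule: str, removed_ids) -> None:
        removed_ids = list(removed_ids)
        self.rules.append((rule, len(removed_ids), removed_ids))

    @property
    def n_removed(self) -> int:
        return sum(n for _, n, _ in self.rules)

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_ids)

    def counts(self) -> dict:
        return {rule: n for rule, n, _ in self.rules}

    def to_dict(self) -> dict:
        return {"n_input": self.n_input,
                "rules": [{"rule": r, "n_removed": n, "removed_ids": ids}
                          for r, n, ids in self.rules],
                "n_surviving": self.n_surviving,
                "notes": self.notes}

    def summary(self) -> str:
        lines = [f"input loci: {self.n_input}"]
        for r, n, _ in self.rules:
            lines.append(f"  removed by {r}: {n}")
        lines.append(f"surviving loci: {self.n_surviving}")
        return "\n".join(lines)


def filter_sites(geno: GenotypeTable, max_missing: float = 0.30,
                 min_qual: float = 50.0, depth_range=(30.0, 240.0),
                 min_maf: float = 0.03,
                 report: FilterReport | None = None
                 ) -> tuple[GenotypeTable, FilterReport]:
    """Apply the per-site filters in a fixed, recorded order.

    Order: missingness > ``max_missing``; quality <= ``min_qual``; mean
    depth outside ``depth_range``; MAF < ``min_maf`` (monomorphic loci are
    MAF 0 and fall here); heterozygous in every sample.  Each rule sees
    only the survivors of the previous rules, so per-rule counts depend on
    the recorded order.
    """
    if geno.n_loci == 0:
        raise ValueError("empty genotype table")
    if max_missing <= 0 or min_qual <= 0 or min_maf <= 0:
        raise ValueError("thresholds must be positive")
    report = report or FilterReport(n_input=geno.n_loci)
    cur = geno

    def apply_rule(name, keep_mask):
        nonlocal cur
        removed = cur.loci["id"][~keep_mask]
        report.add(name, removed)
        cur = cur.subset_loci(np.flatnonzero(keep_mask))

    apply_rule("missingness", cur.missing_rate() <= max_missing)
    apply_rule("quality", cur.loci["qual"].to_numpy() > min_qual)
    d = cur.loci["mean_depth"].to_numpy()
    apply_rule("depth", (d >= depth_range[0]) & (d <= depth_range[1]))
    p = cur.allele_freq()
    maf = np.minimum(p, 1 - p)
    apply_rule("maf", maf >= min_maf)
    het_all = np.array([(cur.dosages[:, j][cur.dosages[:, j] != MISSING] == 1).all()
                        and (cur.dosages[:, j] != MISSING).any()
                        for j in range(cur.n_loci)])
    apply_rule("all_heterozygous", ~het_all)
    report.surviving_ids = list(cur.loci["id"])
    return cur, report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the allele counts, the p-value sums the probabilities of
    every heterozygote count whose probability does not exceed that of the
    observed configuration.  Monomorphic sites return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if nA == 0 or na == 0:
        return 1.0
    hs = np.arange(nA % 2, min(nA, na) + 1, 2)
    log_const = gammaln(n + 1) - gammaln(2 * n + 1) + gammaln(nA + 1) + gammaln(na + 1)
    homA = (nA - hs) // 2
    homa = (na - hs) // 2
    logp = (log_const - gammaln(homA + 1) - gammaln(hs + 1) - gammaln(homa + 1)
            + hs * np.log(2.0))
    probs = np.exp(logp - logp.max())
    probs = probs / probs.sum()
    p_obs = probs[hs == n_Aa][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_filter(geno: GenotypeTable, alpha: float = 1e-4,
               report: FilterReport | None = None
               ) -> tuple[GenotypeTable, FilterReport]:
    """Remove loci with strong exact-test HWE deviations (P < alpha)."""
    report = report or FilterReport(n_input=geno.n_loci)
    counts = geno.genotype_counts()
    pvals = np.array([hwe_exact_test(*c) if c.sum() > 0 else 1.0 for c in counts])
    keep = pvals >= alpha
    report.add("hwe", geno.loci["id"][~keep])
    out = geno.subset_loci(np.flatnonzero(keep))
    report.surviving_ids = list(out.loci["id"])
    return out, report


def _pairwise_r2(geno: GenotypeTable) -> np.ndarray:
    """Squared Pearson correlation of dosages, pairwise-complete observations.

    Zero-variance loci get r^2 = 0 against everything (treated as unlinked).
    """
    X = np.ma.masked_invalid(geno.dosages_float().T)  # loci x individuals
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.ma.corrcoef(X)
    r2 = np.asarray(r.filled(0.0)) ** 2
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(geno: GenotypeTable, r2_max: float = 0.6) -> list:
    """Greedy LD pruning; returns the kept locus IDs.

    While any surviving pair has r^2 >= ``r2_max``, the currently worst
    pair is found and the member with more missing data is removed (ties:
    the larger locus index).
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    r2 = _pairwise_r2(geno)
    missing = geno.missing_mask().sum(axis=0)
    alive = np.ones(geno.n_loci, dtype=bool)
    while True:
        sub = np.where(np.outer(alive, alive), r2, 0.0)
        worst = sub.max()
        if worst < r2_max:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if missing[i] > missing[j]:
            drop = i
        elif missing[j] > missing[i]:
            drop = j
        else:
            drop = max(i, j)
        alive[drop] = False
    return list(geno.loci["id"][alive])


def bh_adjust(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rule; returns rejected indices."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    if not below.any():
        return np.array([], dtype=int)
    kmax = np.max(np.nonzero(below)[0])
    return np.sort(order[:kmax + 1])


def fst_outlier_scan(geno: GenotypeTable, ancestry, fdr_q: float = 0.05):
    """Differentiation outlier scan with genomic-control calibration.

    Per-locus F_ST is computed from cluster allele frequencies weighted by
    mean ancestry; the squared score z^2 = F (n_alleles - K) / (1 - F) is
    chi-square with K-1 df under the null, after dividing by the genomic
    inflation factor lambda = median(z^2) / median(chi^2_{K-1}).  Flags are
    Benjamini-Hochberg rejections at ``fdr_q``.

    ``ancestry`` must expose Q (individuals x K), G (K x loci cluster
    allele frequencies) and K.  With K = 1 the scan is skipped.

    Returns (flags boolean array, calibration record dict).
    """
    K = int(ancestry.K)
    if K < 2:
        return (np.zeros(geno.n_loci, dtype=bool),
                {"skipped": True, "reason": "K=1: no structure to scan against"})
    Q = np.asarray(ancestry.Q)
    G = np.asarray(ancestry.G)
    if G.shape != (K, geno.n_loci):
        raise ValueError("ancestry G shape does not match genotype loci")
    w = Q.mean(axis=0)
    w = w / w.sum()
    pbar = w @ G
    het_within = w @ (G * (1 - G))
    het_total = pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = 1.0 - het_within / het_total
    fst = np.where(het_total <= 0, 0.0, np.clip(fst, 0.0, 1.0 - 1e-12))
    n_alleles = 2.0 * geno.call_counts().mean()
    z2 = fst * (n_alleles - K) / (1.0 - fst)
    lam = float(np.median(z2) / stats.chi2.median(K - 1))
    lam = max(lam, 1e-12)
    pvals = stats.chi2.sf(z2 / lam, K - 1)
    rejected = bh_adjust(pvals, fdr_q)
    flags = np.zeros(geno.n_loci, dtype=bool)
    flags[rejected] = True
    flags[het_total <= 0] = False
    record = {"skipped": False, "lambda": lam, "n_flagged": int(flags.sum()),
              "fdr_q": fdr_q, "fst": fst, "z2": z2, "pvalues": pvals}
    return flags, record


def run_qc(geno: GenotypeTable, max_missing: float = 0.30,
           min_qual: float = 50.0, depth_range=(30.0, 240.0),
           min_maf: float = 0.03, hwe_alpha: float = 1e-4,
           r2_max: float = 0.6, ancestry_fitter=None,
           fdr_q: float = 0.05) -> tuple[GenotypeTable, FilterReport]:
    """Full QC pipeline in the fixed order:
    missingness -> quality -> depth -> MAF -> all-het -> HWE -> LD ->
    differentiation outliers.

    ``ancestry_fitter`` is a callable mapping a GenotypeTable to an
    ancestry model (Q, G, K) for the outlier scan; when None the scan is
    skipped and noted in the report.
    """
    report = FilterReport(n_input=geno.n_loci)
    cur, report = filter_sites(geno, max_missing, min_qual, depth_range,
                               min_maf, report=report)
    cur, report = hwe_filter(cur, alpha=hwe_alpha, report=report)
    kept_ids = set(ld_prune(cur, r2_max=r2_max))
    keep = np.array([i in kept_ids for i in cur.loci["id"]])
    report.add("ld", cur.loci["id"][~keep])
    cur = cur.subset_loci(np.flatnonzero(keep))
    if ancestry_fitter is not None and cur.n_loci > 0:
        model = ancestry_fitter(cur)
        flags, record = fst_outlier_scan(cur, model, fdr_q=fdr_q)
        report.add("fst_outlier", cur.loci["id"][flags])
        report.notes["outlier_scan"] = {
            k: v for k, v in record.items()
            if not isinstance(v, np.ndarray)}
        cur = cur.subset_loci(np.flatnonzero(~flags))
    else:
        report.notes["outlier_scan"] = {"skipped": True,
                                        "reason": "no ancestry model supplied"}
    report.surviving_ids = list(cur.loci["id"])
    return cur, report
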