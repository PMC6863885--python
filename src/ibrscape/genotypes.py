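"""Genotype container and VCF input/output.

Genotypes are biallelic SNP dosages in {0, 1, 2} with -1 marking missing
calls.  Loci are anonymous reduced-representation tags: there is no
chromosomal ordering, so positions are synthetic indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "read_vcf", "write_vcf"]

MISSING = -1


@dataclass
class GenotypeTable:
    """Individuals x loci dosage matrix with per-locus metadata.

    Attributes
    ----------
    dosages : int8 ndarray, shape (n_individuals, n_loci)
        Alternate-allele dosage per call: 0, 1, 2, or -1 (missing).
    loci : DataFrame
        One row per locus with columns ``id``, ``pos``, ``qual``
        (site phred quality) and ``mean_depth``.
    sample_ids : list of str
    """

    dosages: np.ndarray
    loci: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x loci)")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, -1}")
        if len(self.loci) != self.dosages.shape[1]:
            raise ValueError("loci metadata length != number of loci")
        if not self.sample_ids:
            self.sample_ids = [f"ind_{i}" for i in range(self.dosages.shape[0])]
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length != number of individuals")
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing calls."""
        out = self.dosages.astype(float)
        out[self.dosages == MISSING] = np.nan
        return out

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus from non-missing calls only."""
        x = self.dosages_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(x, axis=0) / 2.0

    def call_counts(self) -> np.ndarray:
        """Number of non-missing calls per locus."""
        return np.sum(self.dosages != MISSING, axis=0)

    def missing_rate(self) -> np.ndarray:
        return np.mean(self.dosages == MISSING, axis=0)

    def subset_loci(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(self.dosages[:, idx],
                             self.loci.iloc[idx].reset_index(drop=True),
                             list(self.sample_ids))

    def subset_individuals(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(self.dosages[idx],
                             self.loci.copy(),
                             [self.sample_ids[i] for i in idx])

    def genotype_counts(self) -> np.ndarray:
        """Per-locus counts of (hom-ref, het, hom-alt), shape (n_loci, 3)."""
        d = self.dosages
        return np.stack([(d == g).sum(axis=0) for g in (0, 1, 2)], axis=1)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ibrscape
##contig=<ID=1>
##INFO=<ID=DP,Number=1,Type=Float,Description="Mean sample depth at site">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(geno: GenotypeTable, path: str | Path) -> Path:
    """Write genotypes as an uncompressed VCF 4.2 text file.

    Site QUAL carries the phred quality and INFO/DP the per-locus mean
    depth (declared Float so the value round-trips exactly).
    """
    path = Path(path)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in geno.sample_ids) + "\n")
        for j in range(geno.n_loci):
            row = geno.loci.iloc[j]
            gts = "\t".join(gt_map[int(g)] for g in geno.dosages[:, j])
            fh.write(f"1\t{int(row['pos'])}\t{row['id']}\tA\tT\t"
                     f"{float(row['qual']):.6g}\t.\tDP={float(row['mean_depth']):.6g}\t"
                     f"GT\t{gts}\n")
    return path


def read_vcf(path: str | Path) -> GenotypeTable:
    """Read a VCF into a GenotypeTable (biallelic SNPs, GT field only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages_cols = []
    meta = {"id": [], "pos": [], "qual": [], "mean_depth": []}
    for var in vcf:
        gts = var.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        col = np.where(gts == 0, 0,
                       np.where(gts == 1, 1,
                                np.where(gts == 3, 2, MISSING)))
        dosages_cols.append(col.astype(np.int8))
        meta["id"].append(var.ID or f"{var.CHROM}:{var.POS}")
        meta["pos"].append(var.POS)
        meta["qual"].append(var.QUAL if var.QUAL is not None else np.nan)
        dp = var.INFO.get("DP")
        meta["mean_depth"].append(float(dp) if dp is not None else np.nan)
    vcf.close()
    dosages = np.stack(dosages_cols, axis=1) if dosages_cols else np.empty((len(samples), 0), np.int8)
    return GenotypeTable(dosages, pd.DataFrame(meta), samples)
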