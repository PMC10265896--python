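"""Reference genotype panels.

A :class:`ReferencePanel` is a small in-memory genotype matrix (individuals x
SNPs, dosages 0/1/2) with a variant map, playing the role that a public
reference cohort (e.g. ~500 individuals per continental population) plays in
summary-statistics work: it supplies the authoritative variant map for QC,
allele frequencies, LD for clumping and LD scores, and the per-SNP allele
counts behind Fst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

VARIANT_COLUMNS = ["snp_id", "chrom", "bp", "a1", "a2"]


@dataclass
class ReferencePanel:
    """Genotype matrix plus variant map for one population.

    Parameters
    ----------
    genotypes : ndarray of shape (n_individuals, n_snps)
        Allele dosages in {0, 1, 2}, counting copies of ``a1``.
    variants : DataFrame
        Columns ``snp_id, chrom, bp, a1, a2``; one row per genotype column,
        sorted by (chrom, bp).
    population : str
        Free-form label (e.g. ``"EAS"`` or ``"EUR"``).
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    population: str = ""
    _index: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-d (individuals x SNPs) matrix")
        if self.genotypes.shape[1] != len(self.variants):
            raise ValueError("variant map length does not match genotype columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant map missing columns: {missing}")
        bad = ~np.isin(self.genotypes, (0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be 0, 1 or 2")
        order = np.lexsort((self.variants["bp"].to_numpy(),
                            self.variants["chrom"].astype(str).to_numpy()))
        if not np.array_equal(order, np.arange(len(order))):
            self.variants = self.variants.iloc[order].reset_index(drop=True)
            self.genotypes = self.genotypes[:, order]
        else:
            self.variants = self.variants.reset_index(drop=True)
        self._index = {s: i for i, s in enumerate(self.variants["snp_id"])}

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def column(self, snp_id: str) -> int:
        return self._index[snp_id]

    def allele_freq(self) -> np.ndarray:
        """Frequency of allele ``a1`` per SNP."""
        return self.genotypes.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def hwe_pvalues(self) -> np.ndarray:
        """Chi-squared (1 df) goodness-of-fit test of Hardy-Weinberg per SNP.

        Adequate at panel sizes of a few hundred; monomorphic SNPs get P = 1.
        """
        n = self.n_individuals
        n_hom1 = (self.genotypes == 2).sum(axis=0)
        n_het = (self.genotypes == 1).sum(axis=0)
        f = (2 * n_hom1 + n_het) / (2.0 * n)
        exp = np.stack([n * f**2, 2 * n * f * (1 - f), n * (1 - f) ** 2])
        obs = np.stack([n_hom1, n_het, n - n_hom1 - n_het])
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
        p = stats.chi2.sf(chi2, df=1)
        p[(f == 0) | (f == 1)] = 1.0
        return p

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_vcf(cls, path, population: str = "") -> "ReferencePanel":
        """Load a biallelic-site VCF (plain or gzipped) into a panel.

        Dosages count the ALT allele (``a1`` = ALT, ``a2`` = REF). Sites with
        missing genotypes or more than one ALT allele are skipped.
        """
        from cyvcf2 import VCF

        ids, chroms, bps, a1s, a2s, cols = [], [], [], [], [], []
        vcf = VCF(str(path))
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            gt = var.gt_types  # 0 hom-ref, 1 het, 2 missing-or-unknown? cyvcf2: 3 hom-alt
            dos = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, -1)))
            if (dos < 0).any():
                continue
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            chroms.append(str(var.CHROM))
            bps.append(int(var.POS))
            a1s.append(var.ALT[0])
            a2s.append(var.REF)
            cols.append(dos.astype(np.int8))
        vcf.close()
        variants = pd.DataFrame(
            {"snp_id": ids, "chrom": chroms, "bp": bps, "a1": a1s, "a2": a2s}
        )
        geno = np.column_stack(cols) if cols else np.empty((0, 0), dtype=np.int8)
        return cls(genotypes=geno, variants=variants, population=population)

    def to_vcf(self, path) -> None:
        """Write the panel as an uncompressed VCFv4.2 with GT fields."""
        sep = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##source=crosspop-panel population={self.population}\n")
            samples = "\t".join(f"I{i}" for i in range(self.n_individuals))
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            for j, row in self.variants.iterrows():
                gts = "\t".join(sep[int(g)] for g in self.genotypes[:, j])
                fh.write(
                    f"{row.chrom}\t{row.bp}\t{row.snp_id}\t{row.a2}\t{row.a1}"
                    f"\t.\tPASS\t.\tGT\t{gts}\n"
                )
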