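"""Greedy P-value-ordered selection of independent index SNPs (clumping).

Mirrors the PLINK ``--clump`` procedure on reference-panel genotypes:
significance-ranked SNPs are kept unless they sit within a physical window
of an already-selected index SNP on the same chromosome and exceed an r-squared
threshold with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panels import ReferencePanel

logger = logging.getLogger(__name__)


@dataclass
class IndexSNPSet:
    """Selected index SNPs with the parameters that produced them."""

    table: pd.DataFrame            # discovery records of the index SNPs, + n_clumped
    p_threshold: float
    r2_threshold: float
    window_kb: float

    @property
    def k(self) -> int:
        return len(self.table)

    def report(self) -> pd.DataFrame:
        """Clump report in the familiar PLINK ``.clumped``-style layout."""
        cols = [c for c in ("snp_id", "chrom", "bp", "p", "n_clumped") if c in self.table.columns]
        return self.table[cols].copy()


def clump(
    records: pd.DataFrame,
    panel: ReferencePanel,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    window_kb: float = 1_000,
) -> IndexSNPSet:
    """Select index SNPs by greedy P-value-ordered clumping.

    SNPs with ``p < p_threshold`` are visited in ascending P order (ties
    broken by lower (chrom, bp)); a SNP is selected unless it lies within
    ``window_kb`` of an already-selected index SNP on the same chromosome
    with squared Pearson dosage correlation > ``r2_threshold``. Distance is
    measured index-to-candidate. Output is invariant to input row order.
    """
    sig = records[records["p"] < p_threshold]
    sig = sig[sig["snp_id"].isin(panel.variants["snp_id"])]
    if sig.empty:
        logger.warning("clump: no SNP below the significance threshold")
        empty = records.iloc[0:0].copy()
        empty["n_clumped"] = pd.Series(dtype=int)
        return IndexSNPSet(empty, p_threshold, r2_threshold, window_kb)

    sig = sig.sort_values(["p", "chrom", "bp"], kind="stable").reset_index(drop=True)
    window_bp = window_kb * 1_000
    geno = panel.genotypes.astype(float)
    col = {s: panel.column(s) for s in sig["snp_id"]}

    selected: list[int] = []        # row positions in sig
    n_clumped: list[int] = []
    sel_chrom: list = []
    sel_bp: list = []
    sel_geno: list[np.ndarray] = []
    for i, row in sig.iterrows():
        g = geno[:, col[row.snp_id]]
        independent = True
        for j, k in enumerate(selected):
            if sel_chrom[j] != row.chrom or abs(sel_bp[j] - row.bp) > window_bp:
                continue
            x, y = sel_geno[j], g
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r > r2_threshold:
                independent = False
                n_clumped[j] += 1
                break
        if independent:
            selected.append(i)
            n_clumped.append(0)
            sel_chrom.append(row.chrom)
            sel_bp.append(row.bp)
            sel_geno.append(g)

    out = sig.iloc[selected].copy()
    out["n_clumped"] = n_clumped
    return IndexSNPSet(out.reset_index(drop=True), p_threshold, r2_threshold, window_kb)
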