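"""Reference-panel population-genetic metrics.

Per-SNP quantities contrasted between the significant and non-significant
index-SNP groups:

* LD scores — for each focal SNP, the sum over same-chromosome SNPs within
  a 10 Mb window (self included) of the bias-adjusted squared correlation
  r2 - (1 - r2)/(n - 2), computed per population on reference genotypes
  (flanking SNPs must pass MAF > 0.01 and HWE P > 1e-5 filters);
* cross-population coefficients of variation of LD score (LDCV) and of the
  folded minor allele frequency (MAFCV): two-value CV = (|a-b|/sqrt(2)) /
  mean(a, b);
* Hudson's Fst estimator with sampling correction, a per-SNP proxy for
  differential natural selection;
* the group comparisons: per-phenotype two-sided Mann-Whitney U tests and,
  across phenotypes, an exact sign test on the direction of the group-mean
  difference (the pragmatic reading of a paired "McNemar-style" test on
  group averages; a literal McNemar chi-square on the discordant-pair
  construction is available for transparency).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .panels import ReferencePanel

logger = logging.getLogger(__name__)


def ld_scores(panel: ReferencePanel, window_bp: int = 10_000_000,
              maf_min: float = 0.01, hwe_p_min: float = 1e-5) -> np.ndarray:
    """Bias-adjusted LD score of every panel SNP.

    Focal SNPs always receive a score; flanking SNPs (the focal SNP counts
    as its own flank, contributing r2 = 1 exactly) enter the sum only if
    they pass the MAF and HWE filters.
    """
    n = panel.n_individuals
    if n < 3:
        raise ValueError("LD scores need at least 3 individuals")
    geno = panel.genotypes.astype(float)
    sd = geno.std(axis=0, ddof=0)
    ok_flank = (panel.maf() > maf_min) & (panel.hwe_pvalues() > hwe_p_min) & (sd > 0)

    centered = geno - geno.mean(axis=0)
    denom = np.where(sd > 0, sd, 1.0) * np.sqrt(n)
    std = centered / denom            # columns have unit norm where sd > 0

    chroms = panel.variants["chrom"].astype(str).to_numpy()
    bps = panel.variants["bp"].to_numpy()
    scores = np.zeros(panel.n_snps)
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        bp_c = bps[idx]
        # windows via two-pointer sweep over bp-sorted variants
        lo = np.searchsorted(bp_c, bp_c - window_bp, side="left")
        hi = np.searchsorted(bp_c, bp_c + window_bp, side="right")
        sub = std[:, idx]
        flank_ok = ok_flank[idx]
        for a, i in enumerate(idx):
            cols = np.arange(lo[a], hi[a])
            cols = cols[flank_ok[cols]]
            if sd[i] == 0:
                scores[i] = np.nan
                continue
            r = sub[:, cols].T @ sub[:, a]
            r2 = r * r
            self_mask = idx[cols] == i
            r2[self_mask] = 1.0       # exact self term, no numerical noise
            adj = r2 - (1.0 - r2) / (n - 2)
            scores[i] = adj.sum()
            if not self_mask.any():   # focal SNP failed the flank filters
                scores[i] += 1.0      # adjusted self term r2 = 1
    return scores


def pair_cv(value_1, value_2):
    """Two-value coefficient of variation: (|a-b|/sqrt(2)) / mean(a, b).

    Uses the n-1 sample standard deviation of the pair. Pairs with
    non-positive mean are undefined and returned as NaN.
    """
    a = np.asarray(value_1, dtype=float)
    b = np.asarray(value_2, dtype=float)
    mean = (a + b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (np.abs(a - b) / np.sqrt(2.0)) / mean
    bad = ~(mean > 0)
    if np.any(bad):
        logger.warning("pair_cv: %d pair(s) with non-positive mean flagged NaN",
                       int(np.sum(bad)))
    cv = np.where(bad, np.nan, cv)
    return float(cv) if cv.ndim == 0 else cv


def hudson_fst(f1, n1, f2, n2):
    """Hudson's Fst estimator with sampling correction.

    ``n1``/``n2`` are chromosome counts (2x individuals). Numerator
    (f1-f2)^2 - f1(1-f1)/(n1-1) - f2(1-f2)/(n2-1); denominator
    f1(1-f2) + f2(1-f1). Undefined (NaN) when both populations are fixed
    for the same state. Slightly negative values are legitimate sampling
    artifacts and are not clamped.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any((f1 < 0) | (f1 > 1) | (f2 < 0) | (f2 > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("chromosome counts must be >= 2")
    num = (f1 - f2) ** 2 - f1 * (1 - f1) / (n1 - 1) - f2 * (1 - f2) / (n2 - 1)
    den = f1 * (1 - f2) + f2 * (1 - f1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def snp_group_metrics(paired_table: pd.DataFrame,
                      panel1: ReferencePanel, panel2: ReferencePanel,
                      groups: pd.Series | np.ndarray | None = None) -> pd.DataFrame:
    """Assemble per-SNP LDCV, MAFCV and Fst for a set of (index) SNPs.

    ``paired_table`` must carry ``snp_id``; per-population MAFs come from
    ``maf_1``/``maf_2`` columns when present, else from the panels. LD
    scores are computed on each panel and matched by snp_id.
    """
    snp_ids = paired_table["snp_id"].to_numpy()
    ld1 = pd.Series(ld_scores(panel1), index=panel1.variants["snp_id"])
    ld2 = pd.Series(ld_scores(panel2), index=panel2.variants["snp_id"])
    if "maf_1" in paired_table.columns:
        maf1 = paired_table["maf_1"].to_numpy(dtype=float)
    else:
        maf1 = pd.Series(panel1.maf(), index=panel1.variants["snp_id"]).reindex(snp_ids).to_numpy()
    if "maf_2" in paired_table.columns:
        maf2 = paired_table["maf_2"].to_numpy(dtype=float)
    else:
        maf2 = pd.Series(panel2.maf(), index=panel2.variants["snp_id"]).reindex(snp_ids).to_numpy()
    # Fst uses the panels' allele frequencies (same allele in both)
    af1 = pd.Series(panel1.allele_freq(), index=panel1.variants["snp_id"]).reindex(snp_ids).to_numpy()
    af2 = pd.Series(panel2.allele_freq(), index=panel2.variants["snp_id"]).reindex(snp_ids).to_numpy()

    out = pd.DataFrame({
        "snp_id": snp_ids,
        "ld_score_1": ld1.reindex(snp_ids).to_numpy(),
        "ld_score_2": ld2.reindex(snp_ids).to_numpy(),
        "maf_1": maf1,
        "maf_2": maf2,
    })
    out["ldcv"] = pair_cv(out["ld_score_1"], out["ld_score_2"])
    out["mafcv"] = pair_cv(out["maf_1"], out["maf_2"])
    out["fst"] = hudson_fst(af1, 2 * panel1.n_individuals, af2, 2 * panel2.n_individuals)
    if groups is not None:
        out["group"] = np.asarray(groups)
    return out


def group_compare(metrics: pd.DataFrame, metric_name: str,
                  per_phenotype: bool = True,
                  literal_mcnemar: bool = False) -> dict:
    """Compare a metric between significant and non-significant SNP groups.

    Per phenotype: two-sided Mann-Whitney U (normal approximation with tie
    correction). Across phenotypes: each phenotype contributes a binary
    indicator (significant-group mean < non-significant-group mean) and an
    exact binomial sign test against 0.5 is reported; with
    ``literal_mcnemar`` the McNemar chi-square on the discordant-pair
    construction is added.

    ``metrics`` needs columns ``group`` (significant / non_significant),
    ``phenotype`` (if per_phenotype) and the metric column.
    """
    df = metrics.dropna(subset=[metric_name])
    result: dict = {"metric": metric_name}
    rows = []
    phenos = df["phenotype"].unique() if "phenotype" in df.columns else ["all"]
    for ph in phenos:
        sub = df[df["phenotype"] == ph] if ph != "all" else df
        sig = sub.loc[sub["group"] == "significant", metric_name].to_numpy()
        non = sub.loc[sub["group"] == "non_significant", metric_name].to_numpy()
        if len(sig) == 0 or len(non) == 0:
            logger.warning("group_compare: phenotype %r has an empty group, skipped", ph)
            continue
        if np.ptp(np.concatenate([sig, non])) == 0:
            pval, ustat = 1.0, len(sig) * len(non) / 2.0
        else:
            res = stats.mannwhitneyu(sig, non, alternative="two-sided",
                                     method="asymptotic")
            ustat, pval = float(res.statistic), float(res.pvalue)
        rows.append({"phenotype": ph, "u": ustat, "p": pval,
                     "mean_significant": float(sig.mean()),
                     "mean_non_significant": float(non.mean())})
    per_ph = pd.DataFrame(rows)
    result["per_phenotype"] = per_ph
    if len(per_ph):
        lower = per_ph["mean_significant"] < per_ph["mean_non_significant"]
        n_lower = int(lower.sum())
        n_total = int(len(per_ph))
        sign = stats.binomtest(n_lower, n_total, 0.5, alternative="two-sided")
        result.update(
            n_phenotypes=n_total,
            n_significant_group_lower=n_lower,
            share_significant_group_lower=n_lower / n_total,
            sign_test_p=float(sign.pvalue),
            mean_significant=float(per_ph["mean_significant"].mean()),
            sd_significant=float(per_ph["mean_significant"].std(ddof=1)) if n_total > 1 else np.nan,
            mean_non_significant=float(per_ph["mean_non_significant"].mean()),
            sd_non_significant=float(per_ph["mean_non_significant"].std(ddof=1)) if n_total > 1 else np.nan,
        )
        if literal_mcnemar:
            # discordant pairs: phenotypes where the two group means order
            # one way vs the other; chi-square with 1 df on the two counts
            b, c = n_lower, n_total - n_lower
            chi2 = (b - c) ** 2 / (b + c) if (b + c) else 0.0
            result["mcnemar_chi2"] = float(chi2)
            result["mcnemar_p"] = float(stats.chi2.sf(chi2, df=1))
    return result
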