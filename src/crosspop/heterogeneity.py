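"""Per-SNP trans-ethnic effect heterogeneity and direction concordance.

The heterogeneity statistic for a SNP contrasts its unadjusted target-
population effect with its bias-reduced discovery effect,

    u = (b1 - b2) / sqrt(s1^2 + s2^2 - 2 r_m s1 s2),

where r_m is the *marginal* trans-ethnic genetic correlation of the SNP
set: the correlation of effect estimates disattenuated for estimation
noise under a measurement-error model,

    r_m = S12 / sqrt((S1^2 - mean(se1^2)) (S2^2 - mean(se2^2))).

r_m is computed separately within the significant and non-significant
groups and plugged into the heterogeneity test for that group's SNPs.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust, two_sided_p

logger = logging.getLogger(__name__)


def marginal_correlation(beta1, se1, beta2, se2) -> float:
    """Disattenuated correlation of paired effect estimates.

    Subtracts the mean squared estimation error from each sample variance
    before forming the correlation; if a noise-corrected variance is not
    positive the raw Pearson correlation is returned with a warning.
    Result is clipped to [-1, 1].
    """
    b1 = np.asarray(beta1, dtype=float)
    b2 = np.asarray(beta2, dtype=float)
    s1 = np.asarray(se1, dtype=float)
    s2 = np.asarray(se2, dtype=float)
    if b1.size < 5:
        raise ValueError("marginal_correlation needs at least 5 SNPs")
    cov = np.cov(b1, b2, ddof=1)
    v1 = cov[0, 0] - np.mean(s1**2)
    v2 = cov[1, 1] - np.mean(s2**2)
    if v1 <= 0 or v2 <= 0:
        warnings.warn("noise-corrected variance non-positive; falling back to the "
                      "raw Pearson correlation", stacklevel=2)
        r = np.corrcoef(b1, b2)[0, 1]
    else:
        r = cov[0, 1] / np.sqrt(v1 * v2)
    return float(np.clip(r, -1.0, 1.0))


def heterogeneity_test(b1, s1, b2, s2, r_m: float,
                       adjust: bool = True) -> pd.DataFrame:
    """Per-SNP two-sided heterogeneity test.

    ``b1``/``s1`` are the unadjusted target-population marginal effects and
    their (standardized) SEs; ``b2``/``s2`` the bias-reduced discovery
    effects and their SEs. Returns a DataFrame with ``u, p`` and, when
    ``adjust``, BH-adjusted ``fdr`` across the supplied SNPs.
    """
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    var = s1**2 + s2**2 - 2.0 * r_m * s1 * s2
    if np.any(var <= 0):
        raise ValueError("non-positive variance in the heterogeneity denominator")
    u = (b1 - b2) / np.sqrt(var)
    p = two_sided_p(u)
    out = pd.DataFrame({"u": u, "p": p})
    if adjust:
        out["fdr"] = bh_adjust(np.maximum(p, 1e-300))
        out["heterogeneous"] = out["fdr"] < 0.05
    return out


def direction_concordance(beta1, beta2, groups=None) -> pd.DataFrame:
    """Proportions of sign classes (++, +-, -+, --) per group and overall.

    The first sign is the target population's, the second the discovery's.
    Exact-zero effects are excluded from the classes and reported in a
    separate ``n_zero`` column; ``discordant`` is the +- plus -+ share.
    """
    b1 = np.asarray(beta1, dtype=float)
    b2 = np.asarray(beta2, dtype=float)
    groups = np.asarray(["all"] * b1.size if groups is None else groups)
    rows = []
    for g in list(dict.fromkeys(groups)) + (["all"] if groups is not None and
                                            set(groups) != {"all"} else []):
        sel = np.ones_like(b1, bool) if g == "all" else groups == g
        x, y = b1[sel], b2[sel]
        nonzero = (x != 0) & (y != 0)
        n = int(nonzero.sum())
        if n == 0:
            rows.append({"group": g, "n": 0, "n_zero": int((~nonzero).sum()),
                         "pp": np.nan, "pm": np.nan, "mp": np.nan, "mm": np.nan,
                         "discordant": np.nan})
            continue
        xs, ys = x[nonzero] > 0, y[nonzero] > 0
        pp = float(np.mean(xs & ys))
        pm = float(np.mean(xs & ~ys))
        mp = float(np.mean(~xs & ys))
        mm = float(np.mean(~xs & ~ys))
        rows.append({"group": g, "n": n, "n_zero": int((~nonzero).sum()),
                     "pp": pp, "pm": pm, "mp": mp, "mm": mm,
                     "discordant": pm + mp})
    return pd.DataFrame(rows)


def group_heterogeneity_contrast(het_counts) -> tuple[float, float]:
    """Pearson chi-squared test (no continuity correction) on the 2x2 table
    of heterogeneous / non-heterogeneous x significant / non-significant."""
    table = np.asarray(het_counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 count table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def heterogeneity_by_group(table: pd.DataFrame,
                           group_col: str = "group") -> pd.DataFrame:
    """Group-wise r_m, heterogeneity and discordance summary.

    ``table`` must carry ``beta_1, se_1`` (unadjusted target effects with
    standardized SEs), ``beta_corrected_2, se_corrected_2`` (bias-reduced
    discovery effects) and a group label column. r_m is estimated within
    each group and used for that group's heterogeneity tests (BH within
    group).
    """
    b2col = "beta_corrected_2" if "beta_corrected_2" in table.columns else "beta_2"
    s2col = "se_corrected_2" if "se_corrected_2" in table.columns else "se_2"
    rows = []
    for g, sub in table.groupby(group_col, sort=False):
        if len(sub) < 5:
            logger.warning("heterogeneity_by_group: group %r has < 5 SNPs, skipped", g)
            continue
        r_m = marginal_correlation(sub["beta_1"], sub["se_1"], sub[b2col], sub[s2col])
        het = heterogeneity_test(sub["beta_1"], sub["se_1"], sub[b2col], sub[s2col], r_m)
        conc = direction_concordance(sub["beta_1"], sub[b2col])
        rows.append({
            "group": g,
            "n": len(sub),
            "r_m": r_m,
            "n_heterogeneous": int(het["heterogeneous"].sum()),
            "prop_heterogeneous": float(het["heterogeneous"].mean()),
            "discordant": float(conc.loc[0, "discordant"]),
        })
    return pd.DataFrame(rows)
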