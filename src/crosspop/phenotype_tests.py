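"""Phenotype-level cross-population hypothesis tests.

Given external per-phenotype estimates of SNP heritability in two
populations (h2_1 target, h2_2 discovery, with standard errors) and of the
trans-ethnic genetic correlation rho_g (with SE), this module provides:

* the heritability-difference test
  u = (h2_1 - h2_2) / sqrt(se1^2 + se2^2 - 2 rho_g se1 se2),
* approximate normal tests of H0: rho_g = 0 and H0: rho_g = 1,
* Benjamini-Hochberg adjustment across phenotypes,
* cross-phenotype summaries (Pearson correlation of the heritability
  columns; correlation of the heritability coefficient of variation with
  rho_g).

All tests are two-sided normal tests. Heritability and rho_g estimation
themselves (LD-score regression / trans-ethnic correlation software) are
upstream of this package; estimates are consumed as a delimited table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust, two_sided_p

__all__ = [
    "TestResult", "h2_difference_test", "rho_tests", "bh_adjust",
    "count_rho_less_than_one", "heritability_correlation", "h2cv_vs_rho",
    "analyze_heritability_table",
]

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p: float
    hypothesis: str
    fdr: float | None = None


def h2_difference_test(h2_1, se_1, h2_2, se_2, rho_g, label: str = "") -> TestResult:
    """Two-sided normal test for equal heritability across populations.

    The covariance of the two heritability estimators is taken as
    rho_g * se_1 * se_2, so the denominator variance is
    se_1^2 + se_2^2 - 2 rho_g se_1 se_2.
    """
    var = se_1**2 + se_2**2 - 2.0 * rho_g * se_1 * se_2
    if var <= 0:
        raise ValueError(f"non-positive denominator variance for record {label!r}")
    u = (h2_1 - h2_2) / np.sqrt(var)
    return TestResult(float(u), float(two_sided_p(u)), "h2_1 = h2_2")


def rho_tests(rho_g, se_rho) -> tuple[TestResult, TestResult]:
    """Approximate normal tests of H0: rho_g = 0 and H0: rho_g = 1."""
    if se_rho <= 0:
        raise ValueError("se of rho_g must be positive")
    u0 = rho_g / se_rho
    u1 = (rho_g - 1.0) / se_rho
    return (
        TestResult(float(u0), float(two_sided_p(u0)), "rho_g = 0"),
        TestResult(float(u1), float(two_sided_p(u1)), "rho_g = 1"),
    )


def count_rho_less_than_one(records: pd.DataFrame, fdr_threshold: float = 0.05
                            ) -> tuple[int, float]:
    """Number (and proportion) of phenotypes whose rho_g is significantly
    below one after BH adjustment of two-sided rho_g = 1 P values.

    Records with missing rho_g (e.g. estimates out of range excluded
    upstream) are dropped first.
    """
    df = records.dropna(subset=["rho_g", "se_rho"])
    p1 = np.array([rho_tests(r, s)[1].p for r, s in zip(df["rho_g"], df["se_rho"])])
    fdr = bh_adjust(np.maximum(p1, 1e-300))  # guard deep-tail underflow to 0
    reject = (fdr < fdr_threshold) & (df["rho_g"].to_numpy() < 1)
    return int(reject.sum()), float(reject.mean())


def heritability_correlation(records: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (and t-based P) of the two heritability columns."""
    if len(records) < 3:
        raise ValueError("need at least 3 phenotypes")
    x = records["h2_target"].to_numpy(dtype=float)
    y = records["h2_discovery"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a heritability column")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def h2cv_vs_rho(records: pd.DataFrame) -> tuple[float, float]:
    """Correlation of the per-phenotype heritability CV with rho_g.

    The CV of the heritability pair {h2_1, h2_2} uses the n-1 sample
    standard deviation, |h2_1 - h2_2| / sqrt(2), over the pair mean.
    """
    df = records.dropna(subset=["rho_g"]).copy()
    if len(df) < 3:
        raise ValueError("need at least 3 phenotypes with rho_g")
    mean = (df["h2_target"] + df["h2_discovery"]) / 2.0
    bad = mean <= 0
    if bad.any():
        logger.warning("h2cv_vs_rho: excluded %d record(s) with non-positive "
                       "mean heritability", int(bad.sum()))
        df, mean = df[~bad], mean[~bad]
    cv = (np.abs(df["h2_target"] - df["h2_discovery"]) / np.sqrt(2.0)) / mean
    if np.std(cv) == 0:
        raise ValueError("heritability CV is constant; correlation undefined")
    r, p = stats.pearsonr(cv, df["rho_g"])
    return float(r), float(p)


def analyze_heritability_table(records: pd.DataFrame,
                               fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Run all phenotype-level tests over a heritability/correlation table.

    Expects columns ``phenotype, h2_target, se_target, h2_discovery,
    se_discovery, rho_g, se_rho``; returns the table augmented with the
    heritability-difference statistic/P/FDR and the rho_g = 0 / rho_g = 1
    P values with their BH adjustments (computed over non-missing rows).
    """
    out = records.copy()
    stat, pdiff = [], []
    for _, r in out.iterrows():
        if pd.isna(r.get("rho_g")):
            stat.append(np.nan)
            pdiff.append(np.nan)
            continue
        t = h2_difference_test(r["h2_target"], r["se_target"],
                               r["h2_discovery"], r["se_discovery"],
                               r["rho_g"], label=str(r.get("phenotype", "")))
        stat.append(t.statistic)
        pdiff.append(t.p)
    out["u_h2_diff"] = stat
    out["p_h2_diff"] = pdiff

    for col_p, col_u, which in (("p_rho0", "u_rho0", 0), ("p_rho1", "u_rho1", 1)):
        us, ps = [], []
        for _, r in out.iterrows():
            if pd.isna(r.get("rho_g")):
                us.append(np.nan)
                ps.append(np.nan)
            else:
                t = rho_tests(r["rho_g"], r["se_rho"])[which]
                us.append(t.statistic)
                ps.append(t.p)
        out[col_u] = us
        out[col_p] = ps

    for col in ("p_h2_diff", "p_rho0", "p_rho1"):
        mask = out[col].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = bh_adjust(
                np.maximum(out.loc[mask, col].to_numpy(), 1e-300))
        out["fdr" + col.removeprefix("p")] = adj
    return out
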