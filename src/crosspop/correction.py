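"""Winner's-curse correction and sample-size standard-error standardization.

Index SNPs are selected *because* they crossed the genome-wide significance
threshold in the discovery GWAS, so their observed effects are inflated away
from zero (winner's curse). Under the truncated-normal selection model, the
expected observed effect given the true effect beta is

    E[beta_hat | selected] = beta + s * [phi(beta/s - c) - phi(-beta/s - c)]
                                      / [Psi(beta/s - c) + Psi(-beta/s - c)]

with phi/Psi the standard normal pdf/cdf, s the (pooled) standard error and
c = Psi^{-1}(1 - alpha/2) the selection threshold on the z scale
(c ~ 5.4513 at alpha = 5e-8). The corrector inverts this identity by a
dense grid search for beta over the 95% confidence interval of beta_hat.

The second half of the module removes the discovery/target sample-size
imbalance: target-population standard errors are re-derived from allele
frequency and the *discovery* sample size, se ~ sqrt(1/(N f (1-f)))
(case/control analogue for binary phenotypes), and z and P are recomputed
with the effect held fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import two_sided_p
from .clump import IndexSNPSet

logger = logging.getLogger(__name__)


@dataclass
class CorrectionConfig:
    """Parameters of the truncation model and its grid-search solver."""

    alpha: float = 5e-8
    grid_points: int = 10_001
    ci_multiplier: float = 1.96

    @property
    def c(self) -> float:
        """Selection threshold on the z scale, Psi^{-1}(1 - alpha/2)."""
        return float(stats.norm.isf(self.alpha / 2))


def pooled_se(index_set: IndexSNPSet | pd.DataFrame) -> float:
    """Mean discovery-population SE across the selected index SNPs."""
    table = index_set.table if isinstance(index_set, IndexSNPSet) else index_set
    if len(table) == 0:
        raise ValueError("pooled_se: empty index-SNP set")
    se = table["se_2"] if "se_2" in table.columns else table["se"]
    return float(np.mean(se))


def _conditional_mean(beta: np.ndarray, s: float, c: float) -> np.ndarray:
    """E[beta_hat | |beta_hat/s| > c] under beta_hat ~ Normal(beta, s^2)."""
    z = np.asarray(beta, dtype=float) / s
    num = stats.norm.pdf(z - c) - stats.norm.pdf(-z - c)
    den = stats.norm.sf(c - z) + stats.norm.sf(c + z)  # = Psi(z-c) + Psi(-z-c)
    # den >= Psi(-c) ~ alpha > 0 analytically; guard the deep-tail underflow
    # where both pdf terms are already zero and the bias is negligible.
    safe = den > 0
    out = np.where(safe, beta + s * np.divide(num, den, where=safe, out=np.zeros_like(z)), beta)
    return out


class WinnersCurseCorrector(TransformerMixin, BaseEstimator):
    """Shrink selected discovery effects under the truncated-normal model.

    scikit-learn-style transformer: ``fit`` pools the discovery standard
    errors of the index-SNP set into a single phenotype-level ``s``;
    ``transform`` maps observed effects to bias-reduced ones by grid-search
    inversion of the conditional-mean identity.

    Parameters
    ----------
    alpha : float
        Selection significance level (the genome-wide threshold).
    grid_points : int
        Resolution of the beta search grid.
    ci_multiplier : float
        Half-width of the search interval in units of ``s`` (1.96 spans the
        95% confidence interval of the observed effect).

    Attributes
    ----------
    pooled_se_ : float
        Phenotype-level standard error used inside the truncation model.
    c_ : float
        Selection threshold on the z scale.
    """

    def __init__(self, alpha: float = 5e-8, grid_points: int = 10_001,
                 ci_multiplier: float = 1.96):
        self.alpha = alpha
        self.grid_points = grid_points
        self.ci_multiplier = ci_multiplier

    def fit(self, X, y=None):
        """Pool discovery SEs. ``X`` may be an IndexSNPSet, a DataFrame with
        an ``se``/``se_2`` column, or a 1-d array of standard errors."""
        if isinstance(X, (IndexSNPSet, pd.DataFrame)):
            self.pooled_se_ = pooled_se(X)
        else:
            se = np.asarray(X, dtype=float).ravel()
            if se.size == 0:
                raise ValueError("empty SE vector")
            self.pooled_se_ = float(se.mean())
        if self.pooled_se_ <= 0:
            raise ValueError("pooled SE must be positive")
        self.c_ = CorrectionConfig(self.alpha).c
        return self

    def transform(self, X) -> np.ndarray:
        """Return bias-reduced effects for observed effects ``X`` (1-d)."""
        check_is_fitted(self, "pooled_se_")
        beta_hat = np.asarray(X, dtype=float).ravel()
        s, c = self.pooled_se_, self.c_
        grid_offsets = np.linspace(-self.ci_multiplier * s, self.ci_multiplier * s,
                                   self.grid_points)
        out = np.empty_like(beta_hat)
        below = np.abs(beta_hat) / s < c
        if below.any():
            warnings.warn(
                f"{int(below.sum())} effect(s) below the selection threshold; "
                "returned uncorrected (outside the truncation model)",
                stacklevel=2,
            )
            out[below] = beta_hat[below]
        todo = np.flatnonzero(~below)
        for i in todo:
            grid = beta_hat[i] + grid_offsets
            resid = np.abs(_conditional_mean(grid, s, c) - beta_hat[i])
            # ties broken toward smaller |beta| (more conservative shrinkage)
            best = np.lexsort((np.abs(grid), resid))[0]
            out[i] = grid[best]
        return out


def winners_curse_correct(beta_hat, s: float,
                          config: CorrectionConfig | None = None) -> np.ndarray | float:
    """Functional form of :class:`WinnersCurseCorrector` (scalar or vector)."""
    config = config or CorrectionConfig()
    est = WinnersCurseCorrector(config.alpha, config.grid_points, config.ci_multiplier)
    est.fit([s])
    scalar = np.isscalar(beta_hat)
    out = est.transform(np.atleast_1d(beta_hat))
    return float(out[0]) if scalar else out


def recompute_se_from_z(beta, z):
    """SE implied by a corrected effect at unchanged marginal z: se = beta/z."""
    beta = np.asarray(beta, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z == 0):
        raise ValueError("z = 0: standard error undefined (cannot occur for selected SNPs)")
    out = beta / z
    return float(out) if out.ndim == 0 else out


def standardize_se(f, n=None, binary: bool = False, n_case=None, n_control=None):
    """Approximate SE from allele frequency and (discovery) sample size.

    Continuous: sqrt(1 / (N f (1-f))). Binary:
    sqrt((N1 + N0) / (2 N1 N0 f (1-f))). Symmetric in f <-> 1-f.
    """
    f = np.asarray(f, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    if binary:
        if n_case is None or n_control is None:
            raise ValueError("binary phenotypes require n_case and n_control")
        n_case = np.asarray(n_case, dtype=float)
        n_control = np.asarray(n_control, dtype=float)
        if np.any(n_case <= 0) or np.any(n_control <= 0):
            raise ValueError("sample sizes must be positive")
        out = np.sqrt((n_case + n_control) / (2 * n_case * n_control * f * (1 - f)))
    else:
        n = np.asarray(n, dtype=float)
        if np.any(n <= 0):
            raise ValueError("sample size must be positive")
        out = np.sqrt(1.0 / (n * f * (1 - f)))
    return float(out) if out.ndim == 0 else out


def correct_discovery_effects(paired_table: pd.DataFrame,
                              config: CorrectionConfig | None = None) -> pd.DataFrame:
    """Add winner's-curse-corrected discovery columns to an index-SNP table.

    Adds ``beta_corrected_2`` (shrunken effect) and ``se_corrected_2``
    (= beta_corrected_2 / z_2; the marginal z and P are kept unchanged).
    """
    config = config or CorrectionConfig()
    out = paired_table.copy()
    s = float(out["se_2"].mean())
    out["beta_corrected_2"] = winners_curse_correct(out["beta_2"].to_numpy(), s, config)
    out["se_corrected_2"] = recompute_se_from_z(out["beta_corrected_2"].to_numpy(),
                                                out["z_2"].to_numpy())
    return out


def rescale_target_stats(paired, n_discovery=None, binary: bool = False,
                         n_case=None, n_control=None):
    """Standardize target-population SEs to the discovery sample size.

    Replaces ``se_1`` by the frequency-based SE evaluated at the *discovery*
    population's size(s), keeps ``beta_1`` unchanged, and recomputes ``z_1``
    and ``p_1`` conditional on the new SE. Accepts a PairedSumStats or its
    table; returns the same type.
    """
    from .sumstats import PairedSumStats

    is_paired = isinstance(paired, PairedSumStats)
    table = paired.table.copy() if is_paired else paired.copy()
    if "eaf_1" in table.columns:
        f = table["eaf_1"].to_numpy()
    elif "maf_1" in table.columns:
        f = table["maf_1"].to_numpy()
    else:
        raise ValueError("target allele frequency missing and no panel fallback available")
    if np.any(~np.isfinite(f)):
        raise ValueError("target allele frequency contains missing values")

    if binary:
        nc = table["n_case_2"] if n_case is None else n_case
        n0 = table["n_control_2"] if n_control is None else n_control
        se = standardize_se(f, binary=True, n_case=nc, n_control=n0)
    else:
        n = table["n_2"] if n_discovery is None else n_discovery
        se = standardize_se(f, n=n)
    table["se_standardized_1"] = se
    table["se_1"] = se
    z = table["beta_1"].to_numpy() / np.asarray(se, dtype=float)
    table["z_1"] = z
    table["p_1"] = two_sided_p(z)
    if is_paired:
        return PairedSumStats(table=table, n_dropped=paired.n_dropped,
                              pop1=paired.pop1, pop2=paired.pop2)
    return table
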