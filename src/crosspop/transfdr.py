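"""Trans-ethnic false discovery rate via empirical-Bayes local FDR.

For a set of discovery-significant index SNPs, the trans-ethnic FDR of a SNP
is the posterior probability that it is *not* associated with the phenotype
in the target population, conditional on the significance observed in both
populations. Conditioning on discovery significance is realized by fitting
the two-group model only on the discovery-significant index set; within
that set the quantity is the Efron local FDR of the SNP's (sample-size
standardized) target z score,

    fdr(z) = pi0 * f0(z) / f(z),

with f0 the theoretical standard normal null, f estimated by Poisson-
regression spline smoothing of histogram counts, and pi0 the null
proportion (Storey's estimator at lambda = 0.5, capped at 1). SNPs with
transFDR below the declaration threshold (default 0.05) form the
"significant" (population-common) group, the rest the "non-significant"
(discovery-specific) group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from sklearn.utils.validation import check_is_fitted

from ._utils import bh_adjust, two_sided_p

logger = logging.getLogger(__name__)


@dataclass
class TransFdrConfig:
    """Estimation and declaration parameters for the two-group model."""

    threshold: float = 0.05
    n_bins: int = 120
    spline_df: int = 7
    pi0_lambda: float = 0.5
    min_snps: int = 30

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.n_bins < 20:
            raise ValueError("n_bins must be >= 20")
        if self.spline_df >= self.n_bins:
            raise ValueError("spline_df must be smaller than n_bins")


def _bspline_basis(x: np.ndarray, lo: float, hi: float, df: int, degree: int = 3) -> np.ndarray:
    """Cubic B-spline basis with ``df`` columns on [lo, hi]."""
    n_internal = max(df - degree - 1, 0)
    internal = np.linspace(lo, hi, n_internal + 2)[1:-1]
    t = np.r_[[lo] * (degree + 1), internal, [hi] * (degree + 1)]
    x = np.clip(x, lo, hi)
    return BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()


class LocalFdr(BaseEstimator):
    """Efron-style empirical-Bayes local FDR for two-sided z scores.

    The hypothesis is two-sided, so the model is fit on the magnitudes
    |z|: the null density is the half-normal 2*phi(|z|), the marginal
    density is estimated by Poisson GLM smoothing of histogram counts of
    |z| on a cubic B-spline basis, and the per-bin fdr curve

        fdr(|z|) = pi0 * 2 phi(|z|) / f_hat(|z|)

    is regularized to be monotone non-increasing in |z| by isotonic
    regression. Fitted values therefore depend on z only through |z|.

    Attributes
    ----------
    pi0_ : float
        Estimated null proportion.
    fdr_ : ndarray
        Local fdr of each training observation, clipped to [0, 1].
    bin_mid_, fdr_curve_ : ndarray
        Regularized fdr on the |z| histogram bin midpoints (the
        interpolation table used by :meth:`predict_fdr`).
    """

    def __init__(self, n_bins: int = 120, spline_df: int = 7, pi0_lambda: float = 0.5):
        self.n_bins = n_bins
        self.spline_df = spline_df
        self.pi0_lambda = pi0_lambda

    def fit(self, X, y=None):
        import statsmodels.api as sm

        z = np.asarray(X, dtype=float).ravel()
        a = np.abs(z)
        if z.size < 2 or np.ptp(a) == 0:
            warnings.warn("degenerate z input: returning fdr = 1 for all", stacklevel=2)
            self.pi0_ = 1.0
            self.bin_mid_ = np.array([a.min() if a.size else 0.0])
            self.fdr_curve_ = np.array([1.0])
            self.fdr_ = np.ones_like(z)
            return self

        # null proportion: Storey's estimator on two-sided P values
        p = two_sided_p(z)
        lam = self.pi0_lambda
        self.pi0_ = min(1.0, float(np.mean(p > lam) / (1.0 - lam)))

        lo, hi = 0.0, a.max() + 1e-6 * max(1.0, a.max())
        edges = np.linspace(lo, hi, self.n_bins + 1)
        counts, _ = np.histogram(a, bins=edges)
        mids = 0.5 * (edges[:-1] + edges[1:])
        width = edges[1] - edges[0]

        basis = _bspline_basis(mids, lo, hi, self.spline_df)
        design = sm.add_constant(basis)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = sm.GLM(counts, design, family=sm.families.Poisson()).fit()
        f_hat = np.maximum(fitted.mu, 1e-12) / (z.size * width)

        f0 = 2.0 * stats.norm.pdf(mids)     # half-normal null density of |z|
        raw = np.clip(self.pi0_ * f0 / f_hat, 0.0, 1.0)

        curve = IsotonicRegression(increasing=False).fit_transform(mids, raw)
        self.bin_mid_ = mids
        self.fdr_curve_ = np.clip(curve, 0.0, 1.0)
        self.fdr_ = self.predict_fdr(z)
        return self

    def predict_fdr(self, z) -> np.ndarray:
        """Interpolate the regularized fdr curve at new z values (via |z|)."""
        check_is_fitted(self, "fdr_curve_")
        z = np.asarray(z, dtype=float).ravel()
        return np.interp(np.abs(z), self.bin_mid_, self.fdr_curve_)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).fdr_


def local_fdr(z_values, config: TransFdrConfig | None = None) -> np.ndarray:
    """Per-observation local fdr values (functional wrapper over LocalFdr)."""
    config = config or TransFdrConfig()
    z = np.asarray(z_values, dtype=float).ravel()
    if z.size < config.min_snps:
        warnings.warn(
            f"fewer than {config.min_snps} z values: falling back to the "
            "conservative estimate fdr = 1", stacklevel=2)
        return np.ones_like(z)
    return LocalFdr(config.n_bins, config.spline_df, config.pi0_lambda).fit_predict(z)


@dataclass
class TransFdrResult:
    """Per-SNP transFDR values and the induced two-group classification."""

    table: pd.DataFrame        # snp_id, z_target, transfdr, group
    k: int
    f11: int                   # significant in the target population
    f01: int                   # discovery-only
    pi0: float
    threshold: float
    phenotype: str = ""

    @property
    def detection_proportion(self) -> float:
        return self.f11 / self.k if self.k else float("nan")


class TransFdrClassifier(BaseEstimator):
    """Classify discovery-significant index SNPs in the target population.

    ``fit`` takes the standardized target-population z scores of the index
    set, computes each SNP's transFDR and labels SNPs with transFDR below
    ``threshold`` as significant (population-common). Small sets (fewer
    than ``min_snps``) fall back to Benjamini-Hochberg q-values on the
    target P values as a conservative surrogate.

    Attributes
    ----------
    transfdr_ : ndarray of per-SNP transFDR values in [0, 1]
    labels_ : boolean ndarray, True = significant in the target population
    pi0_ : float
    """

    def __init__(self, threshold: float = 0.05, n_bins: int = 120,
                 spline_df: int = 7, pi0_lambda: float = 0.5, min_snps: int = 30):
        self.threshold = threshold
        self.n_bins = n_bins
        self.spline_df = spline_df
        self.pi0_lambda = pi0_lambda
        self.min_snps = min_snps

    def fit(self, X, y=None):
        z = np.asarray(X, dtype=float).ravel()
        if z.size == 0:
            raise ValueError("empty index-SNP set")
        if z.size < self.min_snps:
            logger.info("TransFdrClassifier: %d SNPs < %d, using BH q-values "
                        "as a conservative transFDR surrogate", z.size, self.min_snps)
            self.transfdr_ = bh_adjust(np.maximum(two_sided_p(z), 1e-300))
            self.pi0_ = 1.0
        else:
            est = LocalFdr(self.n_bins, self.spline_df, self.pi0_lambda).fit(z)
            self.transfdr_ = est.fdr_
            self.pi0_ = est.pi0_
            self.estimator_ = est
        self.labels_ = self.transfdr_ < self.threshold
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def transfdr_classify(paired_selected, config: TransFdrConfig | None = None,
                      phenotype: str = "") -> TransFdrResult:
    """Classify an index-SNP set into significant / non-significant groups.

    Parameters
    ----------
    paired_selected : PairedSumStats or DataFrame
        The harmonized pair restricted to the discovery-significant index
        SNPs, *after* winner's-curse correction and target SE
        standardization (``z_1`` must be the standardized target z score).
        MHC SNPs are excluded before classification.
    """
    from .sumstats import PairedSumStats, exclude_mhc

    config = config or TransFdrConfig()
    table = paired_selected.table if isinstance(paired_selected, PairedSumStats) else paired_selected
    if len(table) == 0:
        raise ValueError("transfdr_classify: empty index-SNP set")
    if {"chrom", "bp"} <= set(table.columns):
        table = exclude_mhc(table)
    clf = TransFdrClassifier(config.threshold, config.n_bins,
                             config.spline_df, config.pi0_lambda, config.min_snps)
    clf.fit(table["z_1"].to_numpy())
    out = pd.DataFrame(
        {
            "snp_id": table["snp_id"].to_numpy(),
            "z_target_standardized": table["z_1"].to_numpy(),
            "transfdr": clf.transfdr_,
            "group": np.where(clf.labels_, "significant", "non_significant"),
        }
    )
    f11 = int(clf.labels_.sum())
    return TransFdrResult(table=out, k=len(out), f11=f11, f01=len(out) - f11,
                          pi0=clf.pi0_, threshold=config.threshold, phenotype=phenotype)


def detection_summary(results) -> tuple[pd.DataFrame, dict]:
    """Per-phenotype detection proportions f11/k and their summary.

    ``results`` may be a collection of :class:`TransFdrResult` or a
    DataFrame with columns ``phenotype, k, f11``. Returns the per-phenotype
    table and a summary dict with the unweighted mean proportion, its
    range, and the share of phenotypes with proportion >= 0.5.
    """
    if isinstance(results, pd.DataFrame):
        df = results[["phenotype", "k", "f11"]].copy()
    else:
        df = pd.DataFrame(
            [{"phenotype": r.phenotype, "k": r.k, "f11": r.f11} for r in results]
        )
    if df.empty:
        raise ValueError("detection_summary: no phenotypes supplied")
    zero = df["k"] == 0
    if zero.any():
        logger.warning("detection_summary: excluded %d phenotype(s) with k = 0",
                       int(zero.sum()))
        df = df[~zero]
    df = df.copy()
    df["proportion"] = df["f11"] / df["k"]
    summary = {
        "mean_proportion": float(df["proportion"].mean()),
        "min_proportion": float(df["proportion"].min()),
        "max_proportion": float(df["proportion"].max()),
        "share_at_least_half": float((df["proportion"] >= 0.5).mean()),
        "n_phenotypes": int(len(df)),
    }
    return df.reset_index(drop=True), summary
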