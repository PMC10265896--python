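"""Synthetic two-population GWAS data with known truth.

The generator emulates the statistical structure that the downstream stages
assume: per-SNP true effects in two ancestral populations drawn with a
controlled trans-ethnic genetic correlation rho_g, estimation noise driven
by per-population heritability and sample size, genome-wide-significance
truncation in the discovery population arising naturally from the noise
model, LD-block structure in the reference panels, and allele-frequency
divergence with a tunable expected Fst (Balding-Nichols model).

Defaults mirror the study conditions this package targets: a large
discovery (European-role) GWAS, a several-fold smaller target (East
Asian-role) GWAS, reference panels of ~500 individuals each, polygenic
heritabilities around 0.1 and a trans-ethnic correlation of 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import two_sided_p
from .panels import ReferencePanel
from .sumstats import PairedSumStats


@dataclass
class TruthConfig:
    """Generating parameters for a paired summary-statistics dataset.

    ``h2_1``/``n1`` refer to the target (EAS-role) population and
    ``h2_2``/``n2`` to the discovery (EUR-role) population. Binary
    phenotypes are emulated at the summary level through case/control
    standard errors; set ``n_case_*``/``n_control_*`` instead of ``n*``.
    """

    m: int = 10_000
    causal_fraction: float = 0.01
    rho_g: float = 0.75
    h2_1: float = 0.08
    h2_2: float = 0.13
    n1: int = 100_000
    n2: int = 500_000
    binary: bool = False
    n_case_1: int | None = None
    n_control_1: int | None = None
    n_case_2: int | None = None
    n_control_2: int | None = None
    fst_level: float = 0.05

    def __post_init__(self):
        if not 0 <= self.h2_1 < 1 or not 0 <= self.h2_2 < 1:
            raise ValueError("heritabilities must lie in [0, 1)")
        if not 0 < self.causal_fraction <= 1:
            raise ValueError("causal_fraction must lie in (0, 1]")
        if not -1 <= self.rho_g <= 1:
            raise ValueError("rho_g must lie in [-1, 1]")


@dataclass
class TruthRecord:
    """Ground truth behind one simulated dataset."""

    beta1: np.ndarray          # true per-allele effects, target population
    beta2: np.ndarray          # true per-allele effects, discovery population
    causal: np.ndarray         # boolean causal indicator
    f1: np.ndarray             # true effect-allele frequencies
    f2: np.ndarray
    config: TruthConfig
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [f"rs{i + 1}" for i in range(len(self.beta1))],
                "beta1_true": self.beta1,
                "beta2_true": self.beta2,
                "causal": self.causal,
                "f1_true": self.f1,
                "f2_true": self.f2,
            }
        )


def _balding_nichols(rng, p_anc: np.ndarray, fst: float) -> np.ndarray:
    """Population frequencies given ancestral ones, E[Fst] = ``fst``."""
    if fst == 0:
        return p_anc.copy()
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)


def generate_panels(
    n1: int = 504,
    n2: int = 503,
    m: int = 2_000,
    block_size: int = 10,
    within_block_r2: float = 0.3,
    fst_level: float = 0.05,
    seed: int = 0,
    bp_spacing: int = 5_000,
    chrom: str = "1",
) -> tuple[ReferencePanel, ReferencePanel]:
    """Generate two diverged reference panels with LD-block structure.

    Ancestral allele frequencies are Uniform(0.05, 0.5); each population's
    frequencies diverge under the Balding-Nichols model with parameter
    ``fst_level``. Haplotypes within a block of ``block_size`` consecutive
    SNPs share a latent Gaussian factor, inducing within-block squared
    dosage correlations of roughly ``within_block_r2`` (the Gaussian
    threshold construction attenuates the latent correlation slightly).
    """
    if min(n1, n2, m, block_size) <= 0:
        raise ValueError("all counts must be positive")
    if not 0 <= fst_level < 1 or not 0 <= within_block_r2 < 1:
        raise ValueError("fst_level and within_block_r2 must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.5, size=m)
    variants = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": chrom,
            "bp": np.arange(1, m + 1) * bp_spacing,
            "a1": "A",
            "a2": "G",
        }
    )
    latent_rho = np.sqrt(within_block_r2)
    block = np.arange(m) // block_size
    n_blocks = block[-1] + 1

    panels = []
    for n_ind, label in ((n1, "pop1"), (n2, "pop2")):
        freq = _balding_nichols(rng, p_anc, fst_level)
        thresh = stats.norm.ppf(freq)
        dosage = np.zeros((n_ind, m), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal((n_ind, n_blocks))[:, block]
            noise = rng.standard_normal((n_ind, m))
            latent = np.sqrt(latent_rho) * shared + np.sqrt(1 - latent_rho) * noise
            dosage += (latent < thresh).astype(np.int8)
        panels.append(
            ReferencePanel(genotypes=dosage, variants=variants.copy(), population=label)
        )
    return panels[0], panels[1]


def _se_for_population(cfg: TruthConfig, which: int, f: np.ndarray) -> np.ndarray:
    """Sampling standard error of the per-allele effect estimate.

    Continuous phenotypes use the exact standardized-phenotype form
    1/sqrt(2 N f (1-f)); binary ones the case/control form
    sqrt((N1+N0) / (2 N1 N0 f (1-f))).
    """
    het = 2.0 * f * (1.0 - f)
    if cfg.binary:
        ncase = cfg.n_case_1 if which == 1 else cfg.n_case_2
        nctrl = cfg.n_control_1 if which == 1 else cfg.n_control_2
        if not ncase or not nctrl:
            raise ValueError("binary phenotypes need n_case and n_control for both populations")
        return np.sqrt((ncase + nctrl) / (ncase * nctrl * het))
    n = cfg.n1 if which == 1 else cfg.n2
    return np.sqrt(1.0 / (n * het))


def generate_paired_sumstats(
    config: TruthConfig,
    panels: tuple[ReferencePanel, ReferencePanel] | None = None,
    seed: int = 0,
) -> tuple[PairedSumStats, TruthRecord]:
    """Draw paired summary statistics with known truth.

    Causal standardized effects follow a bivariate normal with correlation
    ``rho_g`` and per-SNP variance ``h2_k / m_causal``; non-causal effects
    are zero. Standardized effects are converted to the per-allele scale by
    dividing by sqrt(2 f (1-f)). Observed effects add independent Gaussian
    estimation noise with the per-population sampling standard error, which
    is also reported as each record's ``se`` (so ``z = beta/se`` and ``p``
    are internally consistent and E[chi2] = 1 + N h2 / m).
    """
    rng = np.random.default_rng(seed)
    if panels is not None:
        p1, p2 = panels
        m = p1.n_snps
        f1, f2 = p1.allele_freq(), p2.allele_freq()
        variants = p1.variants
    else:
        m = config.m
        p_anc = rng.uniform(0.05, 0.5, size=m)
        f1 = _balding_nichols(rng, p_anc, config.fst_level)
        f2 = _balding_nichols(rng, p_anc, config.fst_level)
        variants = pd.DataFrame(
            {
                "snp_id": [f"rs{i + 1}" for i in range(m)],
                "chrom": "1",
                "bp": np.arange(1, m + 1) * 5_000,
                "a1": "A",
                "a2": "G",
            }
        )
    f1 = np.clip(f1, 1e-3, 1 - 1e-3)
    f2 = np.clip(f2, 1e-3, 1 - 1e-3)

    n_causal = max(1, int(round(m * config.causal_fraction)))
    causal = np.zeros(m, dtype=bool)
    causal[rng.choice(m, size=n_causal, replace=False)] = True

    v1 = config.h2_1 / n_causal
    v2 = config.h2_2 / n_causal
    cov = config.rho_g * np.sqrt(v1 * v2)
    b_std = rng.multivariate_normal([0.0, 0.0], [[v1, cov], [cov, v2]], size=n_causal)
    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    beta1[causal] = b_std[:, 0] / np.sqrt(2 * f1[causal] * (1 - f1[causal]))
    beta2[causal] = b_std[:, 1] / np.sqrt(2 * f2[causal] * (1 - f2[causal]))

    se1 = _se_for_population(config, 1, f1)
    se2 = _se_for_population(config, 2, f2)
    bhat1 = beta1 + rng.standard_normal(m) * se1
    bhat2 = beta2 + rng.standard_normal(m) * se2

    table = pd.DataFrame(
        {
            "snp_id": variants["snp_id"].to_numpy(),
            "chrom": variants["chrom"].astype(str).to_numpy(),
            "bp": variants["bp"].to_numpy(),
            "effect_allele": variants["a1"].to_numpy(),
            "other_allele": variants["a2"].to_numpy(),
            "beta_1": bhat1,
            "se_1": se1,
            "z_1": bhat1 / se1,
            "p_1": two_sided_p(bhat1 / se1),
            "eaf_1": f1,
            "maf_1": np.minimum(f1, 1 - f1),
            "beta_2": bhat2,
            "se_2": se2,
            "z_2": bhat2 / se2,
            "p_2": two_sided_p(bhat2 / se2),
            "eaf_2": f2,
            "maf_2": np.minimum(f2, 1 - f2),
            "allele_flipped": False,
        }
    )
    if config.binary:
        table["n_case_1"], table["n_control_1"] = config.n_case_1, config.n_control_1
        table["n_case_2"], table["n_control_2"] = config.n_case_2, config.n_control_2
    else:
        table["n_1"], table["n_2"] = config.n1, config.n2

    truth = TruthRecord(beta1=beta1, beta2=beta2, causal=causal,
                        f1=f1, f2=f2, config=config, seed=seed)
    return PairedSumStats(table=table), truth


def population_sumstats(paired: PairedSumStats, which: int) -> pd.DataFrame:
    """Extract one population's table in the canonical single-population schema."""
    suf = f"_{which}"
    t = paired.table
    out = pd.DataFrame({"snp_id": t["snp_id"]})
    for col in ("chrom", "bp", "effect_allele", "other_allele"):
        if col in t.columns:
            out[col] = t[col]
    for col in ("beta", "se", "z", "p", "eaf", "maf", "n", "n_case", "n_control"):
        if col + suf in t.columns:
            out[col] = t[col + suf]
    return out
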