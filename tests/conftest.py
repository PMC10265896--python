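import numpy as np
import pandas as pd
import pytest

from crosspop import ReferencePanel, TruthConfig, generate_paired_sumstats, generate_panels


@pytest.fixture(scope="session")
def small_panels():
    """Two 120-individual, 300-SNP panels with LD blocks and mild divergence."""
    return generate_panels(n1=120, n2=120, m=300, block_size=5,
                           within_block_r2=0.3, fst_level=0.05, seed=7)


@pytest.fixture(scope="session")
def paired_with_truth(small_panels):
    cfg = TruthConfig(causal_fraction=0.2, rho_g=0.8, h2_1=0.3, h2_2=0.4,
                      n1=50_000, n2=200_000)
    return generate_paired_sumstats(cfg, panels=small_panels, seed=11)


@pytest.fixture
def tiny_panel():
    """Hand-built 6-SNP panel for QC tests (deterministic genotypes)."""
    rng = np.random.default_rng(3)
    variants = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3", "rs4", "rs5", "rs6"],
            "chrom": ["1", "1", "1", "2", "2", "6"],
            "bp": [100, 200, 300, 100, 200, 30_000_000],
            "a1": ["A", "C", "A", "G", "T", "A"],
            "a2": ["G", "T", "C", "A", "C", "G"],
        }
    )
    geno = rng.integers(0, 3, size=(40, 6)).astype(np.int8)
    return ReferencePanel(genotypes=geno, variants=variants, population="toy")


def make_sumstats(rows, **attrs):
    """Assemble a canonical summary-statistics DataFrame from dict rows."""
    df = pd.DataFrame(rows)
    if "z" not in df.columns and {"beta", "se"} <= set(df.columns):
        df["z"] = df["beta"] / df["se"]
    if "p" not in df.columns and "z" in df.columns:
        from scipy import stats

        df["p"] = 2 * stats.norm.sf(np.abs(df["z"]))
    for k, v in attrs.items():
        df.attrs[k] = v
    return df
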