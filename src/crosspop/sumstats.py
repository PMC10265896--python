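"""Reading, quality control and cross-population harmonization of GWAS
summary statistics.

Summary statistics are carried as pandas DataFrames with a canonical schema
(one row per SNP, one table per population):

====================  =====================================================
column                meaning
====================  =====================================================
``snp_id``            rs identifier
``chrom``             chromosome label (string)
``bp``                1-based base-pair position
``effect_allele``     allele to which ``beta`` refers
``other_allele``      the other allele
``beta``              marginal per-allele effect (or log-odds)
``se``                standard error of ``beta``
``z``                 ``beta / se``
``p``                 two-sided P value
``eaf``               effect-allele frequency (optional)
``maf``               minor allele frequency, ``min(eaf, 1 - eaf)``
``n``                 total sample size (continuous phenotypes)
``n_case, n_control`` case/control sizes (binary phenotypes)
====================  =====================================================

A harmonized pair of populations is a :class:`PairedSumStats`: the two
tables intersected on ``snp_id`` and aligned to a common effect allele, with
target-population columns suffixed ``_1`` and discovery-population columns
suffixed ``_2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import two_sided_p
from .panels import ReferencePanel

logger = logging.getLogger(__name__)

#: canonical column order (missing optional columns are permitted)
COLUMNS = [
    "snp_id", "chrom", "bp", "effect_allele", "other_allele",
    "beta", "se", "z", "p", "eaf", "maf", "n", "n_case", "n_control",
]

_MANDATORY = ["snp_id", "effect_allele", "other_allele", "beta", "se"]
_BASES = frozenset("ACGT")
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

# The major histocompatibility complex has exceptionally long-range LD and is
# excluded from heritability estimation and from transFDR classification.
MHC_CHROM = "6"
MHC_START = 28_500_000
MHC_END = 33_500_000


def read_sumstats(path, schema: dict | None = None, sep=None) -> pd.DataFrame:
    """Read a delimited summary-statistics file into the canonical schema.

    Parameters
    ----------
    path : str or Path
        Header-bearing delimited text file; ``.gz`` is read transparently.
    schema : dict, optional
        Mapping from file column names to canonical field names, for files
        whose headers differ from the canonical ones.
    sep : str, optional
        Field delimiter; by default any run of whitespace (tabs included).

    Rows whose mandatory numeric fields fail to parse are dropped and the
    count is logged at INFO level. Missing ``z``/``p``/``maf`` are derived.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+", engine="python")
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file missing mandatory column(s): {missing}")

    numeric = [c for c in ["bp", "beta", "se", "z", "p", "eaf", "maf",
                           "n", "n_case", "n_control"] if c in df.columns]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    need = [c for c in ["beta", "se"] if c in df.columns]
    before = len(df)
    df = df.dropna(subset=need)
    df = df[df["se"] > 0]
    dropped = before - len(df)
    if dropped:
        logger.info("read_sumstats: dropped %d row(s) with unparseable/invalid numerics", dropped)

    df = df.copy()
    df["snp_id"] = df["snp_id"].astype(str)
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    if "z" not in df.columns:
        df["z"] = df["beta"] / df["se"]
    if "p" not in df.columns:
        df["p"] = two_sided_p(df["z"])
    if "eaf" in df.columns and "maf" not in df.columns:
        df["maf"] = np.minimum(df["eaf"], 1 - df["eaf"])
    df.attrs["n_dropped"] = dropped
    return df.reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path, sep="\t") -> None:
    """Write a summary-statistics table in the canonical text format."""
    cols = [c for c in COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep=sep, index=False, columns=cols)


def qc_filter(records: pd.DataFrame, panel: ReferencePanel) -> pd.DataFrame:
    """Apply the five-step summary-statistics quality control.

    In order: (i) remove all copies of duplicated rs ids; (ii) remove
    non-biallelic variants (allele strings must be single bases and differ);
    (iii) remove records without rs labels; (iv) remove records absent from
    the reference panel or whose allele pair does not match the panel's
    (swapped order allowed); (v) keep MAF > 0.01, backfilling missing MAF
    from the panel. Per-step removal counts are logged and stored in
    ``result.attrs["qc_removed"]``.
    """
    df = records.copy()
    removed = {}

    dup = df["snp_id"].duplicated(keep=False)
    removed["duplicated"] = int(dup.sum())
    df = df[~dup]

    biallelic = (
        df["effect_allele"].isin(_BASES)
        & df["other_allele"].isin(_BASES)
        & (df["effect_allele"] != df["other_allele"])
    )
    removed["non_biallelic"] = int((~biallelic).sum())
    df = df[biallelic]

    has_rs = df["snp_id"].str.startswith("rs")
    removed["no_rs_label"] = int((~has_rs).sum())
    df = df[has_rs]

    pv = panel.variants.set_index("snp_id")
    in_panel = df["snp_id"].isin(pv.index)
    sub = df[in_panel]
    pa1 = pv.loc[sub["snp_id"], "a1"].to_numpy()
    pa2 = pv.loc[sub["snp_id"], "a2"].to_numpy()
    ea, oa = sub["effect_allele"].to_numpy(), sub["other_allele"].to_numpy()
    match = ((ea == pa1) & (oa == pa2)) | ((ea == pa2) & (oa == pa1))
    removed["not_in_panel_or_allele_mismatch"] = int((~in_panel).sum()) + int((~match).sum())
    df = sub[match]

    df = df.copy()
    panel_maf = pd.Series(panel.maf(), index=panel.variants["snp_id"])
    if "maf" not in df.columns:
        df["maf"] = np.nan
    fill = df["maf"].isna()
    df.loc[fill, "maf"] = panel_maf.reindex(df.loc[fill, "snp_id"]).to_numpy()
    keep = df["maf"] > 0.01
    removed["maf_below_0.01"] = int((~keep).sum())
    df = df[keep]

    for step, n in removed.items():
        logger.info("qc_filter step %s: removed %d", step, n)
    if df.empty:
        logger.warning("qc_filter: no records survived quality control")
    out = df.reset_index(drop=True)
    out.attrs["qc_removed"] = removed
    return out


@dataclass
class PairedSumStats:
    """Allele-aligned, intersected per-SNP records for two populations.

    ``table`` holds shared columns (``snp_id, chrom, bp, effect_allele,
    other_allele``), per-population columns suffixed ``_1`` (target role)
    and ``_2`` (discovery role), and a boolean ``allele_flipped`` marking
    records whose population-1 effect was negated during alignment.
    """

    table: pd.DataFrame
    n_dropped: int = 0
    pop1: str = "target"
    pop2: str = "discovery"

    def __len__(self):
        return len(self.table)


def harmonize_pair(
    pop1: pd.DataFrame,
    pop2: pd.DataFrame,
    palindromic_maf_max: float | None = 0.4,
) -> PairedSumStats:
    """Intersect two QC'd tables on ``snp_id`` and align effect alleles.

    Population 2 (the discovery role) is the alignment reference: where the
    effect alleles disagree but the allele pair matches, population 1's beta
    and z are negated and its effect-allele frequency complemented.
    Irreconcilable allele pairs are dropped and counted. Palindromic (A/T,
    C/G) SNPs are kept only when both populations' MAF <
    ``palindromic_maf_max`` (pass ``None`` to keep all).
    """
    merged = pop1.merge(pop2, on="snp_id", suffixes=("_1", "_2"), how="inner")
    if merged.empty:
        raise ValueError("harmonize_pair: zero SNPs in common between the populations")

    ea1, oa1 = merged["effect_allele_1"], merged["other_allele_1"]
    ea2, oa2 = merged["effect_allele_2"], merged["other_allele_2"]
    same = (ea1 == ea2) & (oa1 == oa2)
    swapped = (ea1 == oa2) & (oa1 == ea2)
    keep = same | swapped
    n_dropped = int((~keep).sum())
    merged = merged[keep].copy()
    swapped = swapped[keep]

    merged["allele_flipped"] = swapped.to_numpy()
    flip = merged["allele_flipped"]
    for col in ("beta_1", "z_1"):
        if col in merged.columns:
            merged.loc[flip, col] = -merged.loc[flip, col]
    if "eaf_1" in merged.columns:
        merged.loc[flip, "eaf_1"] = 1.0 - merged.loc[flip, "eaf_1"]
    merged.loc[flip, ["effect_allele_1", "other_allele_1"]] = (
        merged.loc[flip, ["other_allele_1", "effect_allele_1"]].to_numpy()
    )

    if palindromic_maf_max is not None and {"maf_1", "maf_2"} <= set(merged.columns):
        pal = [
            (a, b) in _PALINDROMIC
            for a, b in zip(merged["effect_allele_2"], merged["other_allele_2"])
        ]
        pal = np.asarray(pal)
        unsafe = pal & ~(
            (merged["maf_1"] < palindromic_maf_max)
            & (merged["maf_2"] < palindromic_maf_max)
        ).to_numpy()
        n_dropped += int(unsafe.sum())
        if unsafe.any():
            logger.info("harmonize_pair: dropped %d ambiguous palindromic SNP(s)",
                        int(unsafe.sum()))
        merged = merged[~unsafe].copy()

    # collapse shared site columns
    merged["effect_allele"] = merged["effect_allele_2"]
    merged["other_allele"] = merged["other_allele_2"]
    for col in ("chrom", "bp"):
        if f"{col}_2" in merged.columns:
            merged[col] = merged[f"{col}_2"]
        elif f"{col}_1" in merged.columns:
            merged[col] = merged[f"{col}_1"]
    if n_dropped:
        logger.info("harmonize_pair: dropped %d irreconcilable record(s)", n_dropped)
    return PairedSumStats(table=merged.reset_index(drop=True), n_dropped=n_dropped)


def exclude_mhc(records: pd.DataFrame,
                chrom: str = MHC_CHROM,
                start: int = MHC_START,
                end: int = MHC_END) -> pd.DataFrame:
    """Drop SNPs inside the MHC region (chr6:28.5-33.5 Mb, bounds inclusive)."""
    c = records["chrom"].astype(str).str.removeprefix("chr")
    inside = (c == chrom) & (records["bp"] >= start) & (records["bp"] <= end)
    return records[~inside].reset_index(drop=True)
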