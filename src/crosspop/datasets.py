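"""Bundled example tables.

Two small published-summary tables for 31 complex phenotypes studied in
European (discovery role) and East Asian (target role) cohorts ship with
the package, so the phenotype-level tests and detection summaries can be
run out of the box:

* ``load_heritability_table`` — per-phenotype SNP-heritability estimates in
  each population with standard errors and the trans-ethnic genetic
  correlation estimate with its SE (TG has no usable correlation estimate
  and carries missing values).
* ``load_detection_counts`` — per-phenotype counts of discovery index SNPs
  (k) and how many were / were not declared significant in the target
  population (f11 / f01).
"""

from importlib.resources import files

import pandas as pd

_DATA = files("crosspop") / "data"


def load_heritability_table() -> pd.DataFrame:
    """Heritability / trans-ethnic correlation estimates for 31 phenotypes."""
    return pd.read_csv(str(_DATA / "heritability_table.csv"))


def load_detection_counts() -> pd.DataFrame:
    """Index-SNP detection counts (k, f11, f01) for 31 phenotypes."""
    return pd.read_csv(str(_DATA / "detection_counts.csv"))
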