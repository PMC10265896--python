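"""End-to-end orchestration: QC -> clump -> winner's-curse correction ->
SE standardization -> transFDR -> heterogeneity -> popgen metrics -> group
tests, driven by a YAML config, with a machine-readable run manifest.

Each phenotype block either points at prepared input files or carries a
``synthetic`` block fully specifying a simulated dataset (the synthetic
route generates reference panels and paired summary statistics with known
truth). All randomness flows from the single config seed through per-stage
named substreams, so stage-level reruns are stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import rng_for_stage
from .clump import clump
from .correction import CorrectionConfig, correct_discovery_effects, rescale_target_stats
from .datasets import load_heritability_table
from .heterogeneity import heterogeneity_by_group
from .panels import ReferencePanel
from .phenotype_tests import analyze_heritability_table
from .popgen import group_compare, snp_group_metrics
from .simulate import TruthConfig, generate_paired_sumstats, generate_panels
from .sumstats import PairedSumStats, exclude_mhc, harmonize_pair, qc_filter, read_sumstats
from .transfdr import TransFdrConfig, detection_summary, transfdr_classify

logger = logging.getLogger(__name__)

_TRUTH_FIELDS = {f.name for f in dataclasses.fields(TruthConfig)}
_PANEL_KEYS = {"n1", "n2", "m", "block_size", "within_block_r2", "fst_level",
               "bp_spacing", "chrom"}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> list[str]:
    """Return human-readable problems; an empty list means runnable."""
    problems = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    seed = config.get("seed")
    if seed is None:
        problems.append("missing field: seed")
    elif not isinstance(seed, int) or seed < 0:
        problems.append("seed must be a non-negative integer")
    phenos = config.get("phenotypes") or []
    if not phenos:
        problems.append("config lists zero phenotypes")
    for i, ph in enumerate(phenos):
        name = ph.get("name", f"#{i}")
        if "synthetic" in ph:
            extra = set(ph["synthetic"]) - _TRUTH_FIELDS
            if extra:
                problems.append(f"phenotype {name}: unknown synthetic key(s) {sorted(extra)}")
            if "panel" in ph and (extra2 := set(ph["panel"]) - _PANEL_KEYS):
                problems.append(f"phenotype {name}: unknown panel key(s) {sorted(extra2)}")
        else:
            for key in ("sumstats_target", "sumstats_discovery"):
                p = ph.get(key)
                if not p:
                    problems.append(f"phenotype {name}: missing field {key}")
                elif not Path(p).exists():
                    problems.append(f"phenotype {name}: path does not exist: {p}")
            if ph.get("panel_vcf_target") and not Path(ph["panel_vcf_target"]).exists():
                problems.append(f"phenotype {name}: panel VCF missing: {ph['panel_vcf_target']}")
    htab = config.get("heritability_table")
    if htab not in (None, "bundled") and not Path(htab).exists():
        problems.append(f"heritability table path does not exist: {htab}")
    return problems


def _phenotype_inputs(ph: dict, seed: int):
    """Materialize (paired, panels, truth) for one phenotype block."""
    name = ph["name"]
    if "synthetic" in ph:
        panel_cfg = dict(ph.get("panel") or {})
        rng_seed = rng_for_stage(seed, f"panel:{name}").integers(2**31 - 1)
        panels = generate_panels(seed=int(rng_seed), **panel_cfg)
        truth_cfg = TruthConfig(**ph["synthetic"])
        ss_seed = rng_for_stage(seed, f"sumstats:{name}").integers(2**31 - 1)
        paired, truth = generate_paired_sumstats(truth_cfg, panels=panels,
                                                 seed=int(ss_seed))
        return paired, panels, truth
    pop1 = read_sumstats(ph["sumstats_target"], ph.get("schema_target"))
    pop2 = read_sumstats(ph["sumstats_discovery"], ph.get("schema_discovery"))
    panel1 = ReferencePanel.from_vcf(ph["panel_vcf_target"], "target")
    panel2 = ReferencePanel.from_vcf(ph["panel_vcf_discovery"], "discovery")
    pop1 = qc_filter(pop1, panel1)
    pop2 = qc_filter(pop2, panel2)
    paired = harmonize_pair(pop1, pop2)
    return paired, (panel1, panel2), None


def run_phenotype(ph: dict, seed: int,
                  correction: CorrectionConfig | None = None,
                  transfdr: TransFdrConfig | None = None,
                  clump_params: dict | None = None) -> dict:
    """Run the per-phenotype stages and return their in-memory products."""
    name = ph["name"]
    correction = correction or CorrectionConfig()
    transfdr = transfdr or TransFdrConfig()
    clump_params = clump_params or {}
    paired, panels, truth = _phenotype_inputs(ph, seed)
    panel1, panel2 = panels

    table = exclude_mhc(paired.table)
    from .simulate import population_sumstats
    discovery = population_sumstats(PairedSumStats(table=table), 2)
    index_set = clump(discovery, panel2,
                      p_threshold=clump_params.get("p_threshold", correction.alpha),
                      r2_threshold=clump_params.get("r2_threshold", 0.01),
                      window_kb=clump_params.get("window_kb", 1000))
    selected = table[table["snp_id"].isin(index_set.table["snp_id"])].copy()
    if selected.empty:
        raise RuntimeError(f"phenotype {name}: no genome-wide-significant SNPs")

    selected = correct_discovery_effects(selected, correction)
    binary = bool(ph.get("synthetic", {}).get("binary", ph.get("binary", False)))
    selected = rescale_target_stats(selected, binary=binary)

    result = transfdr_classify(selected, transfdr, phenotype=name)
    selected = selected.merge(result.table[["snp_id", "group"]], on="snp_id")

    het = heterogeneity_by_group(selected.assign(
        se_2=selected["se_corrected_2"]), group_col="group")
    metrics = snp_group_metrics(selected, panel1, panel2, groups=selected["group"])
    metrics["phenotype"] = name
    return {
        "name": name,
        "paired": paired,
        "index_set": index_set,
        "selected": selected,
        "transfdr": result,
        "heterogeneity": het,
        "metrics": metrics,
        "truth": truth,
    }


def run_pipeline(config: dict | str | Path, out_dir=None) -> dict:
    """Run the full analysis; write report tables and a manifest.

    Returns a bundle dict with the detection table, the phenotype-level
    test table, per-group heterogeneity and metric summaries, and per-
    phenotype products.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config:\n" + "\n".join(f"- {p}" for p in problems))
    seed = config["seed"]
    out_dir = Path(out_dir or config.get("output_dir", "crosspop_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    correction = CorrectionConfig(**(config.get("correction") or {}))
    tf_config = TransFdrConfig(**(config.get("transfdr") or {}))
    clump_params = config.get("clumping") or {}

    products = []
    for ph in config["phenotypes"]:
        stage = f"phenotype:{ph['name']}"
        try:
            products.append(run_phenotype(ph, seed, correction, tf_config, clump_params))
        except Exception:
            (out_dir / "FAILED").write_text(f"stage {stage} failed\n")
            logger.exception("pipeline aborted at stage %s", stage)
            raise

    detection, det_summary = detection_summary([p["transfdr"] for p in products])
    detection["f01"] = detection["k"] - detection["f11"]
    detection = detection[["phenotype", "k", "f11", "f01", "proportion"]]
    detection.to_csv(out_dir / "detection_table.tsv", sep="\t", index=False)

    htab_cfg = config.get("heritability_table")
    if htab_cfg is not None:
        htab = load_heritability_table() if htab_cfg == "bundled" else pd.read_csv(htab_cfg)
        pheno_tests = analyze_heritability_table(htab)
        pheno_tests.to_csv(out_dir / "phenotype_tests.tsv", sep="\t", index=False)
    else:
        pheno_tests = None

    het_all = pd.concat(
        [p["heterogeneity"].assign(phenotype=p["name"]) for p in products],
        ignore_index=True)
    het_all.to_csv(out_dir / "heterogeneity_summary.tsv", sep="\t", index=False)

    metrics_all = pd.concat([p["metrics"] for p in products], ignore_index=True)
    metrics_all.to_csv(out_dir / "snp_metrics.tsv", sep="\t", index=False)
    comparisons = {m: group_compare(metrics_all, m) for m in ("ldcv", "mafcv", "fst")}

    manifest = {
        "seed": seed,
        "config": config,
        "correction": dataclasses.asdict(correction),
        "transfdr": dataclasses.asdict(tf_config),
        "clumping": {"p_threshold": clump_params.get("p_threshold", correction.alpha),
                     "r2_threshold": clump_params.get("r2_threshold", 0.01),
                     "window_kb": clump_params.get("window_kb", 1000)},
        "detection_summary": det_summary,
        "group_comparisons": {
            m: {k: v for k, v in c.items() if not isinstance(v, pd.DataFrame)}
            for m, c in comparisons.items()
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)

    return {
        "detection": detection,
        "detection_summary": det_summary,
        "phenotype_tests": pheno_tests,
        "heterogeneity": het_all,
        "metrics": metrics_all,
        "group_comparisons": comparisons,
        "products": products,
        "manifest": manifest,
    }
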