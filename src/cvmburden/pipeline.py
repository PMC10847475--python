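"""End-to-end orchestration: filter -> weight -> collapse -> test -> enrich.

``run_all`` executes the whole analysis from input paths and parameters,
writing per-stage TSVs and a JSON run manifest (parameters, seeds, and
record counts at each stage).  Re-running with the same configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import burden, ewce, pathways, variants

logger = logging.getLogger("cvmburden")

__all__ = ["DEFAULT_PARAMS", "load_config", "run_all"]

DEFAULT_PARAMS: dict[str, Any] = {
    "popmax_max": 1e-4,
    "ac_max": 3,
    "min_qualified": 10,
    "thresholds": list(burden.DEFAULT_THRESHOLDS),
    "n_perm": 1000,
    "lambda_storey": 0.5,
    "seed": 0,
    "weight_table": "functional",
    "hit_alpha": 0.05,
    "n_boot": 1000,
}

RESULT_COLUMNS = [
    "gene",
    "n_qualified_variants",
    "case_carriers",
    "control_carriers",
    "odds_ratio",
    "p_combined",
    "q_value",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML run configuration, filling parameter defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    config = {"inputs": doc.get("inputs", {}), "outdir": doc.get("outdir", "results")}
    params = dict(DEFAULT_PARAMS)
    params.update(doc.get("params", {}))
    config["params"] = params
    return config


def _resolve_weight_table(spec: str) -> variants.WeightTable:
    if spec in variants.BUILTIN_WEIGHT_TABLES:
        return variants.BUILTIN_WEIGHT_TABLES[spec]
    if Path(spec).exists():
        return variants.WeightTable.from_yaml(spec)
    raise PipelineError(
        f"weight table {spec!r} is neither a builtin name "
        f"({', '.join(variants.BUILTIN_WEIGHT_TABLES)}) nor an existing file"
    )


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return wrapped
    return decorator


def analyze_cohort(
    variant_table: pd.DataFrame,
    carrier_table: pd.DataFrame,
    label_table: pd.DataFrame,
    weight_table: "variants.WeightTable | str" = "functional",
    popmax_max: float = 1e-4,
    ac_max: int = 3,
    min_qualified: int = 10,
    thresholds: tuple[float, ...] = tuple(burden.DEFAULT_THRESHOLDS),
    lambda_storey: float = 0.5,
) -> pd.DataFrame:
    """In-memory burden analysis: filter -> weight -> collapse -> test -> q.

    Returns the per-gene results DataFrame (one row per eligible gene) with
    q-values attached, sorted by combined p.
    """
    if isinstance(weight_table, str):
        table = _resolve_weight_table(weight_table)
    else:
        table = weight_table
    var = variants.select_canonical(variant_table)
    if "cohort_ac" not in var.columns or var["cohort_ac"].isna().any():
        var = variants.compute_cohort_ac(var, carrier_table)
    var = variants.filter_urv(var, popmax_max, ac_max)
    var = variants.assign_weights(var, table)
    genes = burden.eligible_genes(var, min_qualified)
    eligible = var[var["gene"].isin(genes)]
    keep = carrier_table[carrier_table["variant_id"].isin(eligible["variant_id"])]
    matrix = burden.collapse_burden(
        eligible, keep, label_table["sample_id"].tolist(), genes
    )
    results = burden.gene_burden_test(matrix, label_table, thresholds, eligible)
    results["q_value"] = burden.qvalues_storey(
        results["p_combined"].to_numpy(), lambda_storey
    )
    return results.sort_values(
        ["p_combined", "gene"], kind="mergesort"
    ).reset_index(drop=True)


def run_all(config: Mapping[str, Any]) -> dict[str, Any]:
    """Run the full pipeline; returns the manifest (also written to disk).

    ``config`` carries ``inputs`` (paths: variant_table, carrier_table,
    label_table; optional genesets GMT, expression_dir MTX bundle,
    proband_table), ``params`` (thresholds and seeds, see DEFAULT_PARAMS)
    and ``outdir``.
    """
    inputs = config.get("inputs", {})
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    outdir = Path(config.get("outdir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)

    for key in ("variant_table", "carrier_table", "label_table"):
        if key not in inputs:
            raise PipelineError(f"missing required input {key!r}")
        if not Path(inputs[key]).exists():
            raise PipelineError(f"input {key!r} not found: {inputs[key]}")

    manifest: dict[str, Any] = {"params": params, "inputs": dict(inputs),
                                "counts": {}}
    counts = manifest["counts"]

    var = _stage("read_variants")(variants.read_variant_table)(inputs["variant_table"])
    carriers = _stage("read_carriers")(variants.read_carrier_table)(
        inputs["carrier_table"]
    )
    labels = _stage("read_labels")(variants.read_label_table)(inputs["label_table"])
    counts["variants_input"] = int(len(var))
    counts["carrier_records"] = int(len(carriers))
    counts["samples"] = int(len(labels))
    counts["cases"] = int((labels["status"] == "case").sum())

    var = _stage("select_canonical")(variants.select_canonical)(var)
    if "cohort_ac" not in var.columns or var["cohort_ac"].isna().any():
        var = _stage("cohort_ac")(variants.compute_cohort_ac)(var, carriers)
    var = _stage("filter_urv")(variants.filter_urv)(
        var, params["popmax_max"], params["ac_max"]
    )
    counts["variants_after_urv_filter"] = int(len(var))

    table = _resolve_weight_table(str(params["weight_table"]))
    var = _stage("assign_weights")(variants.assign_weights)(var, table)
    counts["qualified_variants"] = int((var["weight"] != 0).sum())

    genes = _stage("eligible_genes")(burden.eligible_genes)(
        var, params["min_qualified"]
    )
    counts["eligible_genes"] = int(len(genes))
    if not genes:
        raise PipelineError("stage 'eligible_genes' failed: no gene has enough "
                            "qualified variants")

    eligible_var = var[var["gene"].isin(genes)]
    keep_carriers = carriers[
        carriers["variant_id"].isin(eligible_var["variant_id"])
    ]
    matrix = _stage("collapse_burden")(burden.collapse_burden)(
        eligible_var, keep_carriers, labels["sample_id"].tolist(), genes
    )

    thresholds = tuple(float(t) for t in params["thresholds"])
    results = _stage("gene_burden_test")(burden.gene_burden_test)(
        matrix, labels, thresholds, eligible_var
    )
    results["q_value"] = burden.qvalues_storey(
        results["p_combined"].to_numpy(), params["lambda_storey"]
    )
    results = results.sort_values(
        ["p_combined", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    results[RESULT_COLUMNS].to_csv(outdir / "burden_results.tsv", sep="\t",
                                   index=False)
    counts["genes_q_lt_0.05"] = int((results["q_value"] < 0.05).sum())
    counts["genes_p_lt_0.05"] = int((results["p_combined"] < 0.05).sum())

    expected = _stage("permutation_qq")(burden.permute_expected_pvalues)(
        matrix, labels, thresholds, int(params["n_perm"]), int(params["seed"])
    )
    qq = expected.copy()
    qq["observed_p"] = np.sort(results["p_combined"].to_numpy())
    qq.to_csv(outdir / "qq.tsv", sep="\t", index=False)
    manifest["lambda_gc"] = burden.genomic_inflation_lambda(
        results["p_combined"].to_numpy()
    )

    hits = results.loc[results["p_combined"] < params["hit_alpha"], "gene"].tolist()
    counts["hit_genes"] = len(hits)
    if inputs.get("genesets"):
        genesets = pathways.read_gmt(inputs["genesets"])
        if hits:
            enrich = _stage("pathway_enrichment")(
                pathways.hypergeometric_enrichment
            )(hits, genesets, genes)
            enrich.to_csv(outdir / "pathway_enrichment.tsv", sep="\t", index=False)
            counts["pathways_tested"] = int(len(enrich))

    if inputs.get("expression_dir"):
        counts_mat, expr_genes, cells = _stage("read_expression")(
            ewce.read_expression_mtx
        )(inputs["expression_dir"])
        spec = _stage("specificity")(ewce.specificity_all_stages)(
            counts_mat, expr_genes, cells
        )
        targets = [g for g in hits if g in spec.index]
        if targets:
            enr = _stage("ewce_bootstrap")(ewce.ewce_bootstrap)(
                targets, spec, int(params["n_boot"]), int(params["seed"])
            )
            enr.to_csv(outdir / "celltype_enrichment.tsv", sep="\t", index=False)
            counts["ewce_groups"] = int(len(enr))
            counts["ewce_target_genes"] = len(targets)

    manifest_path = outdir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("manifest written to %s", manifest_path)
    return manifest
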