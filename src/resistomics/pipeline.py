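"""End-to-end orchestration of the four analysis stages.

Stage order: metabolite screen -> master regulator analysis -> joint
pathway analysis -> survival screen.  Each stage writes its result
table under the output directory; a manifest records every file with
its SHA-256 checksum together with the seed, configuration and input
checksums, so a fixed (config, inputs, seed) triple reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, jointpath, metabolites, mra, survival
from ._rng import substream
from .config import AnalysisConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineInputs", "PipelineError", "run_pipeline"]


@dataclass
class PipelineInputs:
    """File paths for one pipeline run."""

    regulons: str
    deg_table: str
    pathway_membership: str
    pathway_edges: str
    pathway_node_types: str
    metabolites: str
    survival: str

    @classmethod
    def from_dir(cls, bundle_dir: str | Path) -> "PipelineInputs":
        d = Path(bundle_dir)
        return cls(
            regulons=str(d / "regulons.gmt"),
            deg_table=str(d / "deg_table.tsv"),
            pathway_membership=str(d / "pathway_membership.gmt"),
            pathway_edges=str(d / "pathway_edges.tsv"),
            pathway_node_types=str(d / "pathway_node_types.tsv"),
            metabolites=str(d / "metabolites.tsv"),
            survival=str(d / "survival.tsv"),
        )


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying error."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: AnalysisConfig, inputs: PipelineInputs,
                 out_dir: str | Path) -> dict:
    """Run all stages and return the output-file manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, path in dataclasses.asdict(inputs).items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {name!r}: {path} not found")

    manifest: dict = {
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {k: {"path": v, "sha256": _sha256(v)}
                   for k, v in dataclasses.asdict(inputs).items()},
        "outputs": {},
        "stages_completed": [],
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    # ---- stage 1: metabolite screen ------------------------------------
    stage = "metabolite_stats"
    try:
        values, groups = io.read_metabolite_table(inputs.metabolites)
        matrix = metabolites.MetaboliteMatrix(values, groups)
        anova = metabolites.anova_per_metabolite(
            matrix, log_transform=config.log_transform,
            multiple_testing=config.multiple_testing
            if config.multiple_testing != "none" else "none")
        reference = matrix.group_labels[0]
        normalized = metabolites.reference_normalize(matrix, reference)
        k = min(config.top_k_metabolites,
                int((~anova["degenerate"] & anova["p"].notna()).sum()))
        order = metabolites.top_k_cluster_order(normalized, anova, k)
        heat = normalized[order].T
        heat.insert(0, "metabolite", heat.index)
        anova_path = out / "metabolite_anova.tsv"
        heat_path = out / "metabolite_heatmap.tsv"
        io.write_table(anova, anova_path)
        io.write_table(heat.reset_index(drop=True), heat_path)
        record("metabolite_anova", anova_path)
        record("metabolite_heatmap", heat_path)
        # differential enrichment is called at ANOVA P < 0.05 (the screen's
        # significance level); BH-adjusted p is reported alongside
        sig_metabolites = set(
            anova.loc[anova["p"].notna() & (anova["p"] < 0.05), "metabolite"])
        manifest["stages_completed"].append(stage)
    except Exception as err:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, err) from err

    # ---- stage 2: master regulator analysis ----------------------------
    stage = "regulon_mra"
    try:
        regulons = io.read_gmt(inputs.regulons)
        deg_table = io.read_table(inputs.deg_table, io.DEG_SCHEMA)
        mra_result = mra.run_mra(
            regulons, deg_table, config, rng=substream(config.seed, stage))
        mra_path = out / "mra_results.tsv"
        io.write_table(mra_result, mra_path)
        record("mra_results", mra_path)
        sig_genes = mra.deg_set_from_table(
            deg_table, config.deg_padj_cutoff, config.deg_lfc_cutoff)
        n_gene_universe = deg_table["gene"].nunique()
        manifest["stages_completed"].append(stage)
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    # ---- stage 3: joint pathway analysis -------------------------------
    stage = "joint_pathway"
    try:
        pathways = jointpath.load_pathways(
            inputs.pathway_membership, inputs.pathway_edges,
            inputs.pathway_node_types)
        jp_result = jointpath.run_joint_pathway(
            sig_genes, sig_metabolites, pathways,
            gene_universe_size=n_gene_universe,
            metabolite_universe_size=matrix.values.shape[1],
            config=config)
        jp_path = out / "joint_pathway.tsv"
        io.write_table(jp_result, jp_path)
        record("joint_pathway", jp_path)
        manifest["stages_completed"].append(stage)
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    # ---- stage 4: survival screen --------------------------------------
    stage = "survival_screen"
    try:
        cohort = io.read_table(inputs.survival, io.SURVIVAL_SCHEMA)
        ms = survival.median_split(cohort)
        scan = survival.cutpoint_scan(cohort, config)
        scan_path = out / "cutpoint_scan.tsv"
        io.write_table(scan.table, scan_path)
        record("cutpoint_scan", scan_path)
        summary = {
            "median_split": {
                "cutoff": ms.cutoff,
                "logrank_stat": ms.logrank_stat,
                "logrank_p": ms.logrank_p,
                "hr": ms.cox.hr,
                "ci_low": ms.cox.ci_low,
                "ci_high": ms.cox.ci_high,
            },
            "optimal_cutoff": {
                "chosen_cutoff": scan.chosen_cutoff,
                "rule": scan.chosen_rule,
                **scan.notes,
            },
        }
        summary_path = out / "survival_summary.json"
        with open(summary_path, "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        record("survival_summary", summary_path)
        manifest["stages_completed"].append(stage)
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d stages, outputs in %s",
                len(manifest["stages_completed"]), out)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
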