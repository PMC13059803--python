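"""End-to-end orchestration: QC -> imputation -> differential -> conservation
(-> ortholog enrichment), with a JSON manifest that records every parameter,
the seed, the dropped replicates, the imputation pool bounds, and the counts
surviving each filter, so a run can be audited and reproduced from the
manifest alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .conservation import (
    PreyMembership,
    conserved_dotplot_table,
    pca_replicates,
    shared_prey,
    upset_counts,
    upset_counts_table,
)
from .differential import Thresholds, call_prey, differential_table
from .enrichment import run_enrichment
from .impute import ImputationConfig, impute_missing
from .io import read_lfq_table, write_results
from .matrix import DEFAULT_CONTROL_LABEL, LFQMatrix
from .qc import drop_outlier_replicates

log = logging.getLogger("acylscan")


@dataclass
class PipelineConfig:
    lfq_path: str | None = None
    layout: str = "wide"
    control_label: str = DEFAULT_CONTROL_LABEL
    run_qc: bool = True
    grubbs_alpha: float = 0.05
    impute_fraction: float = 0.10
    impute_scope: str = "whole_dataset"
    fc_min: float = 2.0
    adjp_max: float = 0.1
    k_min: int = 6
    log2: bool = False
    seed: int = 0
    out_dir: str = "results"
    reference_path: str | None = None
    pairs_path: str | None = None
    universe_path: str | None = None


@dataclass
class PipelineResult:
    differential: pd.DataFrame
    membership: PreyMembership
    shared: set[str]
    dotplot: pd.DataFrame
    qc_report: pd.DataFrame | None
    pca_variance: pd.DataFrame
    manifest: dict
    enrichment: object | None = None
    pca: object | None = None
    sample_conditions: dict[str, str] | None = None


def run_all(config: PipelineConfig, matrix: LFQMatrix | None = None) -> PipelineResult:
    """Run the full analysis on ``matrix`` (or read it from config.lfq_path)."""
    if matrix is None:
        if config.lfq_path is None:
            raise ValueError("either a matrix or config.lfq_path is required")
        matrix = read_lfq_table(
            config.lfq_path, layout=config.layout, control_label=config.control_label
        )
    manifest: dict = {
        "acylscan_version": __version__,
        "parameters": asdict(config),
        "n_proteins": matrix.n_proteins,
        "n_samples": matrix.n_samples,
        "conditions": matrix.conditions,
    }

    qc_report = None
    if config.run_qc:
        matrix, qc_report = drop_outlier_replicates(matrix, alpha=config.grubbs_alpha)
        dropped = qc_report["dropped_sample"].dropna().tolist()
        manifest["dropped_replicates"] = dropped
        log.info("replicate QC dropped %d sample(s): %s", len(dropped), dropped)

    imputed = impute_missing(
        matrix,
        ImputationConfig(
            fraction=config.impute_fraction,
            pool_scope=config.impute_scope,
            seed=config.seed,
        ),
    )
    manifest["imputation"] = {
        "pool_bounds": list(imputed.pool_bounds),
        "n_imputed_cells": imputed.n_imputed(),
    }

    diff = differential_table(imputed, control_label=config.control_label)
    thresholds = Thresholds(fc_min=config.fc_min, adjp_max=config.adjp_max)
    membership_by_bait, gate, prey_universe = call_prey(diff, thresholds)
    membership = PreyMembership.from_differential(diff, thresholds)
    shared = shared_prey(membership, config.k_min)
    exclusive, marginals = upset_counts(membership)
    dotplot = conserved_dotplot_table(diff, shared, adjp_max=config.adjp_max)

    pca = pca_replicates(imputed, log2=config.log2)
    pca_var = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(pca.component_count)],
            "variance_fraction": pca.variance_fraction,
        }
    )

    manifest["filter_cascade"] = {
        "tested_per_bait": {
            b: int(diff.loc[diff["bait"] == b, "tested"].sum()) for b in matrix.baits
        },
        "fc_pass_per_bait": {b: len(s) for b, s in sorted(membership_by_bait.items())},
        "gate_pass": len(gate),
        "prey_universe": len(prey_universe),
        f"shared_at_k{config.k_min}": len(shared),
        "shared_at_all_baits": len(shared_prey(membership, len(matrix.baits))),
    }
    manifest["pca"] = {
        "variance_fraction": [float(v) for v in pca.variance_fraction[:5]],
        "n_variables_used": pca.n_variables_used,
        "n_variables_dropped": pca.n_variables_dropped,
    }

    enrichment = None
    if config.reference_path and config.pairs_path:
        enrichment = run_enrichment(
            shared, config.reference_path, config.pairs_path, config.universe_path
        )
        manifest["enrichment"] = {
            "x": enrichment.input.x,
            "n_ref": enrichment.input.n_ref,
            "m_nonref": enrichment.input.m_nonref,
            "k_draw": enrichment.input.k_draw,
            "p_value": enrichment.p_value,
            **enrichment.mapping_report,
        }

    return PipelineResult(
        differential=diff,
        membership=membership,
        shared=shared,
        dotplot=dotplot,
        qc_report=qc_report,
        pca_variance=pca_var,
        manifest=manifest,
        enrichment=enrichment,
        pca=pca,
        sample_conditions={s.sample_id: s.condition for s in matrix.samples},
    )


def write_pipeline_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, str]:
    """Write every result table plus the manifest; returns files written."""
    tables = {
        "differential": result.differential,
        "shared_prey": pd.DataFrame({"protein": sorted(result.shared)}),
        "upset_counts": upset_counts_table(result.membership),
        "dotplot": result.dotplot,
        "pca_variance": result.pca_variance,
    }
    if result.qc_report is not None:
        tables["qc_report"] = result.qc_report
    return write_results(tables, out_dir, manifest=result.manifest)
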