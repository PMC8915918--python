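"""End-to-end orchestration: cluster -> burst -> enrich -> select -> assess.

One :class:`RunConfig` holds every tunable constant with its conventional
default (0.7 cut height; MCC >= 0.1, p <= 0.05, >= 3 actives; 50 mg/kg
very-toxic threshold; 1,000 µM activity threshold; 20,000 Monte-Carlo
replicates).  :func:`run_pipeline` executes the stages in dependency order,
writes every module's CSV output plus ``report.json`` and a ``manifest.json``
with config, seed, versions and output checksums, and logs funnel counts at
each stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import assessment, data_io, enrichment, hitcalls, selection
from .clustering import cluster_chemicals
from .enrichment import EnrichmentThresholds

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("acutoxmap")


@dataclass
class RunConfig:
    """All pipeline constants in one place (see module docstring)."""

    chemicals_path: Optional[str] = None
    fingerprints_path: Optional[str] = None
    assays_path: Optional[str] = None
    cut_height: float = 0.7
    ward_dialect: str = "D2"
    mcc_min: float = 0.1
    p_max: float = 0.05
    min_active: int = 3
    very_toxic_threshold: float = 50.0
    activity_threshold: float = 1000.0
    mc_reps: int = 20000
    seed: int = 0
    burst_strict_below: bool = True
    missing_bound_policy: str = "no-burst-filter"
    global_default_bound: float = 1000.0
    merge_ghs_above_5000: bool = False
    cytotoxicity_assay_exclude: list[str] = field(default_factory=list)
    scope: str = "both"  # "global" | "cluster" | "both"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def thresholds(self) -> EnrichmentThresholds:
        return EnrichmentThresholds(self.mcc_min, self.p_max, self.min_active)


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    chemicals=None,
    fps=None,
    assays=None,
) -> dict:
    """Run every stage and write the result bundle under ``outdir``.

    Inputs may be passed in memory (as produced by
    :mod:`acutoxmap.simulate`) or read from the paths in ``config``.
    Returns the report dictionary that is also written to ``report.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if chemicals is None:
        if not (config.chemicals_path and config.fingerprints_path and config.assays_path):
            raise ValueError("no in-memory inputs and no input paths configured")
        chemicals, fps, assays = data_io.read_inputs(
            config.chemicals_path, config.fingerprints_path, config.assays_path
        )
    chemicals = data_io.derive_toxicity_labels(
        chemicals, merge_above_5000=config.merge_ghs_above_5000
    )
    log.info("stage labels: %d chemicals", len(chemicals))

    clusters = cluster_chemicals(
        fps,
        cut_height=config.cut_height,
        dialect=config.ward_dialect,
        all_chem_ids=[c.chem_id for c in chemicals],
    )
    log.info("stage clustering: %d clusters", clusters.n_clusters)

    assays = hitcalls.apply_burst_filter(
        assays,
        chemicals,
        missing_bound_policy=config.missing_bound_policy,
        global_default_bound=config.global_default_bound,
        strict_below=config.burst_strict_below,
    )
    funnel = hitcalls.activity_summary(chemicals, assays)
    log.info("stage burst filter:\n%s", funnel)

    thr = config.thresholds()
    enr_toxic = enrichment.run_enrichment("toxic_vs_all", chemicals, assays, thresholds=thr)
    enr_very = enrichment.run_enrichment(
        "verytoxic_vs_verytoxic_plus_nontoxic",
        chemicals,
        assays,
        thresholds=thr,
        very_toxic_threshold=config.very_toxic_threshold,
    )
    enr_cluster = enrichment.run_enrichment(
        "cluster_toxics_vs_all_toxics", chemicals, assays, clusters, thresholds=thr
    )
    log.info(
        "stage enrichment: %d/%d/%d results (toxic/verytoxic/cluster)",
        len(enr_toxic), len(enr_very), len(enr_cluster),
    )

    report: dict = {
        "funnel_counts": funnel.to_dict(orient="index"),
        "n_clusters": clusters.n_clusters,
    }
    outputs = []

    def write(df, name):
        path = out / name
        data_io._write_csv(df, path)
        outputs.append(path)

    write(
        data_io.chemicals_to_frame(chemicals), "chemicals_labeled.csv"
    )
    import pandas as pd

    write(
        pd.DataFrame(
            {"chem_id": clusters.chem_ids, "cluster_id": clusters.cluster_id}
        ),
        "clusters.csv",
    )
    burst_rows, burst_cols = np.nonzero(assays.tested)
    write(
        pd.DataFrame(
            {
                "chem_id": [assays.chem_ids[i] for i in burst_rows],
                "assay_id": [assays.assay_ids[j] for j in burst_cols],
                "burst_hit": assays.burst_hit[burst_rows, burst_cols],
            }
        ),
        "burst_hits.csv",
    )
    write(enrichment.enrichment_to_frame(enr_toxic), "enrichment_toxic_vs_all.csv")
    write(enrichment.enrichment_to_frame(enr_very), "enrichment_verytoxic.csv")
    write(enrichment.enrichment_to_frame(enr_cluster), "enrichment_cluster.csv")

    global_sel = None
    if config.scope in ("global", "both"):
        global_sel = selection.select_global(
            chemicals, assays, enr_toxic, enr_very,
            exclude_assays=config.cytotoxicity_assay_exclude,
        )
        write(selection.selection_to_frame([global_sel]), "selection_global.csv")
        report["global_selection"] = {
            "n_assays": len(global_sel.selected_assays),
            "covered_toxics": len(global_sel.covered_toxics),
            "uncovered_toxics": len(global_sel.uncovered_toxics),
            "flagged_nontoxics": len(global_sel.flagged_nontoxics),
            "selection_fdr": global_sel.selection_fdr,
        }
        log.info(
            "stage global selection: %d assays, FDR %.3f",
            len(global_sel.selected_assays), global_sel.selection_fdr,
        )

    cluster_assay_map: dict[int, list[str]] = {}
    if config.scope in ("cluster", "both"):
        cluster_sels, summary = selection.per_cluster_selection(
            chemicals, clusters, assays, enr_cluster, enr_toxic, enr_very,
            exclude_assays=config.cytotoxicity_assay_exclude,
        )
        write(selection.selection_to_frame(cluster_sels), "selection_clusters.csv")
        cluster_assay_map = {s.cluster_id: s.selected_assays for s in cluster_sels}
        report["cluster_selection"] = summary
        log.info(
            "stage cluster selection: %d clusters, union %d assays, pooled FDR %.3f",
            summary["n_clusters_selected"],
            summary["union_assay_count"],
            summary["pooled_selection_fdr"],
        )

    activities = assessment.compute_composite_activity(
        chemicals, clusters, cluster_assay_map, assays,
        activity_threshold=config.activity_threshold,
    )
    write(assessment.composite_to_frame(activities), "composite_activity.csv")
    rng = np.random.default_rng(config.seed)
    table, p_bin, odds = assessment.binary_association(activities, chemicals)
    ghs_table, p_ghs = assessment.ghs_association(
        activities, chemicals, n_reps=config.mc_reps, seed=rng
    )
    spans, span_summary = assessment.cluster_ghs_span(clusters, chemicals)
    report["association"] = {
        "binary_table": table.tolist(),
        "binary_fisher_p": p_bin,
        "odds_ratio": odds,
        "ghs_table": ghs_table.to_numpy().tolist(),
        "ghs_categories": [int(c) for c in ghs_table.columns],
        "ghs_montecarlo_p": p_ghs,
        "mc_reps": config.mc_reps,
    }
    report["ghs_span"] = span_summary
    log.info(
        "stage assessment: odds ratio %.3f, binary p %.3g, GHS MC p %.3g",
        odds, p_bin, p_ghs,
    )

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    outputs.append(out / "report.json")
    data_io.write_manifest(
        out / "manifest.json", dataclasses.asdict(config), config.seed, outputs
    )
    return report
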