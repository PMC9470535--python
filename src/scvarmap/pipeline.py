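"""End-to-end orchestration over a synthetic (or user-supplied) cohort.

simulate -> filter somatic calls -> map variants per cell -> enrichment
contrasts -> QC + DEGs -> ORA -> pathway scores -> arm-level CNV ->
hierarchical cell labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from . import cnv as _cnv
from . import expression as _expr
from . import filters as _filters
from . import mapper as _mapper
from . import simulate as _sim
from . import stats as _stats

DEFAULT_CONTRASTS = [
    ("tumor", "normal_duct"),
    ("panin", "normal_duct"),
    ("tumor", "panin"),
]


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces, keyed by stage."""

    ground_truth: _sim.GroundTruth
    somatic_pass: pd.DataFrame
    somatic_fail: pd.DataFrame
    cell_counts: pd.DataFrame
    genotype_labels: pd.DataFrame
    enrichment: _stats.MutationEnrichmentResults
    qc_report: pd.DataFrame
    degs: pd.DataFrame
    ora: dict[str, pd.DataFrame]
    pathway_scores: pd.DataFrame
    pathway_members: dict[str, list[str]]
    arm_matrix: pd.DataFrame
    alteration_events: pd.DataFrame
    cell_labels: pd.DataFrame
    spatial: pd.DataFrame
    extras: dict[str, Any] = field(default_factory=dict)


def run_pipeline(
    cfg: _sim.SimulationConfig,
    contrasts: list[tuple[str, str]] | None = None,
) -> PipelineResult:
    """Run the full analysis on a freshly simulated cohort."""
    contrasts = contrasts or DEFAULT_CONTRASTS

    # variant filtering on the multi-caller call set
    records, call_truth = _sim.simulate_callsets(cfg)
    somatic_pass, somatic_fail = _filters.filter_somatic(records)

    # per-cell mutation mapping on the planted variant sites
    obs, gt = _sim.simulate_read_observations(cfg)
    gt.callset_truth = call_truth
    counts = _mapper.dedup_umis(obs, variants=gt.variants)
    labels = _mapper.classify_cells(counts)

    groups = gt.cells.set_index("barcode")["group"]
    model = _stats.MutationEnrichmentModel(counts, groups, contrasts)
    enrichment = model.fit()

    # expression: QC, normalize, tumor-subcluster DEGs, ORA, pathway scores
    adata = _sim.simulate_expression(cfg)
    gt.program_genes = adata.uns["ground_truth_programs"]
    gt.qc_fail_barcodes = adata.uns["qc_fail_barcodes"]
    kept, qc_report = _expr.qc_filter_cells(adata)
    kept = _expr.normalize_log(kept)
    tumor = kept[kept.obs["group"] == "tumor"].copy()
    degs = _expr.find_degs(tumor, cluster_key="cluster", profile="subcluster")
    gene_sets = _sim.make_gene_sets(cfg)
    universe = _expr.detection_universe(tumor)
    ora = {
        cl: _expr.ora_hypergeometric(
            degs.loc[degs["cluster"] == cl, "gene"].tolist(), gene_sets, universe
        )
        for cl in tumor.obs["cluster"].unique()
    }
    scores, members = _expr.pathway_scores(tumor, ora, cluster_key="cluster")

    # CNV: arm means and deep events
    cnv_mat, deep_truth = _sim.simulate_cnv_matrix(cfg)
    gt.deep_events = deep_truth
    gt.arm_shifts = [list(e) for e in cfg.arm_events]
    bands = _sim.band_table(cfg)
    arm_map, _ = _cnv.map_genes_to_arms(list(cnv_mat.columns), bands)
    arm_matrix = _cnv.arm_level_means(cnv_mat, arm_map)
    cnv_events = _cnv.call_deep_events(cnv_mat)

    # hierarchical per-cell alteration labels: mutations + deep CNV events
    site_gene = gt.variants.set_index(
        ["chrom", "pos", "ref", "alt"]
    )["gene"]
    mut = labels[labels["label"].isin(["variant", "variant_reference"])].copy()
    mut["gene"] = [
        site_gene.get(t, None)
        for t in mut[_mapper.SITE_COLS].itertuples(index=False, name=None)
    ]
    mut_events = mut[["cell_barcode", "gene"]].assign(kind="mutation")
    events = pd.concat([mut_events, cnv_events], ignore_index=True)
    cell_labels = _mapper.label_cells_hierarchical(events)

    spatial = _expr.spatial_distinct_clusters(
        tumor.obs, pd.DataFrame(cfg.samples, columns=["sample_id", "x_mm", "y_mm"])
    )

    return PipelineResult(
        ground_truth=gt,
        somatic_pass=somatic_pass,
        somatic_fail=somatic_fail,
        cell_counts=counts,
        genotype_labels=labels,
        enrichment=enrichment,
        qc_report=qc_report,
        degs=degs,
        ora=ora,
        pathway_scores=scores,
        pathway_members=members,
        arm_matrix=arm_matrix,
        alteration_events=events,
        cell_labels=cell_labels,
        spatial=spatial,
    )
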