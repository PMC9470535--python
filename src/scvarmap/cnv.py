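"""Arm-level summarization of gene-level CNV matrices and deep-event calls.

Consumes any per-cell gene-level copy-number-like matrix (for example the
gene-level output of an expression-based CNV caller), maps genes to
chromosome arms through a cytoband table, and reports the unweighted mean
value per (cell, arm). Deep events — gain or loss of more than one copy —
are thresholded per cell and gene (or arm) and feed the hierarchical cell
labeler. The input scale is declared, not guessed: "copy" means neutral is
1.0 on a copy-number-like scale; "log-ratio" inputs are converted as 2**x.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def map_genes_to_arms(
    genes: list[str],
    band_table: pd.DataFrame,
    centromeres: pd.DataFrame | None = None,
) -> tuple[pd.Series, list[str]]:
    """Gene -> "chrom{p,q}" arm labels from a cytoband (or coordinate) table.

    ``band_table`` needs columns (gene, chrom, band); the arm is the band's
    leading 'p'/'q'. Alternatively pass (gene, chrom, start) plus a
    ``centromeres`` table (chrom, position): genes starting before the
    centromere are 'p', the rest 'q'. Returns (mapping, unmapped genes);
    contradictory rows for a gene raise.
    """
    if "band" in band_table.columns:
        arms = band_table["band"].astype(str).str.extract(r"^.*?([pq])", expand=False)
        if arms.isna().any():
            bad = band_table.loc[arms.isna(), "gene"].tolist()
            raise ValueError(f"bands without a p/q arm for genes: {bad[:5]}")
        mapped = band_table.assign(arm=band_table["chrom"].astype(str) + arms)
    elif centromeres is not None and "start" in band_table.columns:
        cen = centromeres.set_index(centromeres["chrom"].astype(str))["position"]
        chrom = band_table["chrom"].astype(str)
        arm_letter = np.where(
            band_table["start"].to_numpy() < cen.reindex(chrom).to_numpy(), "p", "q"
        )
        mapped = band_table.assign(arm=chrom + arm_letter)
    else:
        raise ValueError("band_table needs a 'band' column or coordinates+centromeres")

    per_gene = mapped.groupby("gene", observed=True)["arm"].unique()
    conflicts = per_gene[per_gene.map(len) > 1]
    if len(conflicts):
        raise ValueError(
            f"contradictory arm assignments for gene(s): {list(conflicts.index)[:5]}"
        )
    arm_of = per_gene.map(lambda a: a[0])
    unmapped = [g for g in genes if g not in arm_of.index]
    return arm_of.reindex([g for g in genes if g in arm_of.index]), unmapped


def arm_level_means(mat: pd.DataFrame, arm_map: pd.Series) -> pd.DataFrame:
    """Unweighted per-(cell, arm) mean over the arm's mapped genes.

    ``mat`` is cells x genes; genes absent from ``arm_map`` are excluded;
    arms with no mapped genes are omitted.
    """
    genes = [g for g in mat.columns if g in arm_map.index]
    if not genes:
        return pd.DataFrame(index=mat.index)
    sub = mat[genes]
    return sub.T.groupby(arm_map.reindex(genes)).mean().T


def call_deep_events(
    mat: pd.DataFrame,
    gain_threshold: float = 2.0,
    loss_threshold: float = 0.25,
    scale: str = "copy",
) -> pd.DataFrame:
    """Deep copy-number events per cell and gene (or arm).

    On the copy-number-like scale (neutral 1.0), a value >= gain_threshold
    is a gain of more than one copy and a value <= loss_threshold a deep
    loss; "log-ratio" inputs are first converted with 2**x. Returns an
    AlterationEvent table (cell_barcode, gene, kind).
    """
    if scale not in ("copy", "log-ratio"):
        raise ValueError("scale must be 'copy' or 'log-ratio'")
    vals = mat.to_numpy(dtype=float)
    if scale == "log-ratio":
        vals = 2.0 ** vals
    gains = np.argwhere(vals >= gain_threshold)
    losses = np.argwhere(vals <= loss_threshold)
    rows = [
        {"cell_barcode": mat.index[i], "gene": mat.columns[j], "kind": "cnv_gain"}
        for i, j in gains
    ] + [
        {"cell_barcode": mat.index[i], "gene": mat.columns[j], "kind": "cnv_loss"}
        for i, j in losses
    ]
    return pd.DataFrame(rows, columns=["cell_barcode", "gene", "kind"])
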