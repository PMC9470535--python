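"""Per-cell mutation mapping from barcoded, UMI-tagged allele observations.

Reads sharing a (cell barcode, site, UMI) triple are duplicates of one
original molecule and collapse to a single consensus call: the strict
majority allele of the duplicate reads. A molecule with a tied vote, or
whose majority is neither ref nor alt, is discarded (and accounted for), so
ref_molecules + alt_molecules + discarded_umis always equals the number of
distinct UMIs seen at that site in that cell. Cells are then classified as
reference / variant / variant_reference / none, and cells carrying several
alterations receive one display label through a fixed gene hierarchy
(mutations outrank copy-number events; KRAS > CDKN2A > SMAD4 > TP53).

Barcode equivalence is exact string match; correction belongs upstream.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

SITE_COLS = ["chrom", "pos", "ref", "alt"]
DEFAULT_GENE_ORDER = ["KRAS", "CDKN2A", "SMAD4", "TP53"]

COUNT_COLUMNS = [
    "cell_barcode",
    *SITE_COLS,
    "ref_molecules",
    "alt_molecules",
    "discarded_umis",
]


def _empty_counts() -> pd.DataFrame:
    return pd.DataFrame(columns=COUNT_COLUMNS)


def dedup_umis(
    obs: pd.DataFrame,
    variants: pd.DataFrame | None = None,
    collapse: bool = True,
) -> pd.DataFrame:
    """Collapse duplicate reads to molecules and count alleles per cell.

    Parameters
    ----------
    obs
        Read-observation table (chrom, pos, ref, alt, cell_barcode, umi,
        observed_allele).
    variants
        Optional site list; observations outside it are dropped first.
    collapse
        When False, skip UMI consensus and count raw reads instead
        (each ref/alt read is one "molecule"; "other" reads are discarded).
    """
    if variants is not None and not obs.empty:
        keys = set(map(tuple, variants[SITE_COLS].itertuples(index=False)))
        mask = [
            t in keys for t in obs[SITE_COLS].itertuples(index=False, name=None)
        ]
        obs = obs.loc[mask]
    if obs.empty:
        return _empty_counts()

    if not collapse:
        grp = obs.groupby(["cell_barcode", *SITE_COLS], sort=True, observed=True)
        out = grp["observed_allele"].agg(
            ref_molecules=lambda a: int((a == "ref").sum()),
            alt_molecules=lambda a: int((a == "alt").sum()),
            discarded_umis=lambda a: int((a == "other").sum()),
        )
        return out.reset_index()

    # votes per molecule: distinct (cell, site, umi)
    votes = (
        obs.groupby(["cell_barcode", *SITE_COLS, "umi"], sort=True, observed=True)[
            "observed_allele"
        ]
        .value_counts()
        .unstack(fill_value=0)
    )
    for col in ("ref", "alt", "other"):
        if col not in votes.columns:
            votes[col] = 0
    v = votes[["ref", "alt", "other"]].to_numpy()
    top = v.max(axis=1)
    n_top = (v == top[:, None]).sum(axis=1)
    winner_idx = v.argmax(axis=1)
    # strict majority required; ties and "other" majorities are discarded
    consensus = np.where(
        (n_top > 1) | (winner_idx == 2),
        "discard",
        np.where(winner_idx == 0, "ref", "alt"),
    )
    mol = votes.index.to_frame(index=False)[["cell_barcode", *SITE_COLS]]
    mol["consensus"] = consensus
    counts = (
        mol.groupby(["cell_barcode", *SITE_COLS], sort=True, observed=True)[
            "consensus"
        ]
        .value_counts()
        .unstack(fill_value=0)
    )
    for col in ("ref", "alt", "discard"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts.rename(
        columns={
            "ref": "ref_molecules",
            "alt": "alt_molecules",
            "discard": "discarded_umis",
        }
    )
    return counts.reset_index()[COUNT_COLUMNS]


def classify_cells(counts: pd.DataFrame, min_molecules: int = 1) -> pd.DataFrame:
    """Label each (cell, site) as reference / variant / variant_reference / none.

    A side is "called" when it has at least ``min_molecules`` consensus
    molecules; both sides called gives variant_reference, neither gives
    none.
    """
    if counts.empty:
        return pd.DataFrame(columns=["cell_barcode", *SITE_COLS, "label"])
    ref_ok = counts["ref_molecules"].to_numpy() >= min_molecules
    alt_ok = counts["alt_molecules"].to_numpy() >= min_molecules
    label = np.select(
        [ref_ok & alt_ok, alt_ok, ref_ok],
        ["variant_reference", "variant", "reference"],
        default="none",
    )
    out = counts[["cell_barcode", *SITE_COLS]].copy()
    out["label"] = label
    return out


def label_cells_hierarchical(
    events: pd.DataFrame, gene_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Reduce each cell's alteration events to one display label.

    Mutations outrank copy-number events regardless of gene; within a kind
    the highest-ranked gene wins. Genes absent from ``gene_order`` rank
    after it, alphabetically. Returns one row per cell with >= 1 event:
    (cell_barcode, gene, kind, display_label).
    """
    order = list(gene_order) if gene_order is not None else list(DEFAULT_GENE_ORDER)
    if events.empty:
        return pd.DataFrame(columns=["cell_barcode", "gene", "kind", "display_label"])

    known = {g: i for i, g in enumerate(order)}
    extra = sorted(set(events["gene"]) - set(order))
    rank = {**known, **{g: len(order) + i for i, g in enumerate(extra)}}

    ev = events.copy()
    ev["_kind_rank"] = (ev["kind"] != "mutation").astype(int)  # mutations first
    ev["_gene_rank"] = ev["gene"].map(rank)
    ev = ev.sort_values(["cell_barcode", "_kind_rank", "_gene_rank", "kind"])
    best = ev.groupby("cell_barcode", sort=True, observed=True).head(1)
    out = best[["cell_barcode", "gene", "kind"]].reset_index(drop=True)
    out["display_label"] = out["gene"] + " " + out["kind"]
    return out


def detect_minority_hotspots(
    obs: pd.DataFrame,
    hotspot_sites: pd.DataFrame,
    cell_samples: pd.Series | None = None,
    collapse: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the mapping pipeline restricted to hotspot sites.

    Returns ``(per_cell_counts, per_sample)``. The per-sample table
    aggregates molecules over cells (optionally grouped by a cell->sample
    mapping) and reports the aggregate VAF; a hotspot with no ref or alt
    coverage in a sample is reported with a missing VAF ("NA": no coverage
    for mutant or reference allele).
    """
    counts = dedup_umis(obs, variants=hotspot_sites, collapse=collapse)
    if counts.empty:
        per_cell = _empty_counts()
    else:
        per_cell = counts

    if cell_samples is None:
        sample_of = pd.Series("all", index=per_cell["cell_barcode"].unique())
    else:
        sample_of = cell_samples
    samples = sorted(sample_of.unique()) if len(sample_of) else ["all"]

    rows = []
    for site in hotspot_sites[SITE_COLS].itertuples(index=False, name=None):
        site_counts = per_cell[
            (per_cell[SITE_COLS] == pd.Series(site, index=SITE_COLS)).all(axis=1)
        ] if not per_cell.empty else per_cell
        for sample in samples:
            if not site_counts.empty:
                in_sample = site_counts["cell_barcode"].map(sample_of) == sample
                sub = site_counts.loc[in_sample.fillna(False)]
            else:
                sub = site_counts
            alt = int(sub["alt_molecules"].sum()) if not sub.empty else 0
            ref = int(sub["ref_molecules"].sum()) if not sub.empty else 0
            n_cells_alt = int((sub["alt_molecules"] > 0).sum()) if not sub.empty else 0
            vaf = alt / (alt + ref) if (alt + ref) > 0 else np.nan
            rows.append(
                {
                    "sample_id": sample,
                    "chrom": site[0],
                    "pos": site[1],
                    "ref": site[2],
                    "alt": site[3],
                    "alt_molecules": alt,
                    "ref_molecules": ref,
                    "cells_with_alt": n_cells_alt,
                    "vaf": vaf,
                    "no_coverage": (alt + ref) == 0,
                }
            )
    return per_cell, pd.DataFrame(rows)


def observations_from_sam(
    sam_path: str,
    variants: pd.DataFrame,
    cell_tag: str = "CB",
    umi_tag: str = "UB",
) -> pd.DataFrame:
    """Optional SAM/BAM adapter: build the observation table by pileup.

    Extracts the cell and molecular barcodes from the given alignment tags
    and reads the base overlapping each 1-based variant position; bases
    matching ref/alt are recorded as such, anything else as "other". Reads
    without both tags, or not covering the site, are skipped. SNV sites
    only — indel support in 3' scRNA data is out of scope.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(sam_path) as af:
        for site in variants[SITE_COLS].itertuples(index=False, name=None):
            chrom, pos, ref, alt = site
            if len(ref) != 1 or len(alt) != 1:
                continue
            for col in af.pileup(str(chrom), pos - 1, pos, truncate=True,
                                 min_base_quality=0):
                for pr in col.pileups:
                    if pr.is_del or pr.is_refskip or pr.query_position is None:
                        continue
                    aln = pr.alignment
                    if not (aln.has_tag(cell_tag) and aln.has_tag(umi_tag)):
                        continue
                    base = aln.query_sequence[pr.query_position].upper()
                    allele = "ref" if base == ref else "alt" if base == alt else "other"
                    rows.append(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "ref": ref,
                            "alt": alt,
                            "cell_barcode": aln.get_tag(cell_tag),
                            "umi": aln.get_tag(umi_tag),
                            "observed_allele": allele,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "cell_barcode", "umi",
                 "observed_allele"],
    )
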