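"""Consensus somatic filtering, germline filtering, hotspot VAF genotyping.

The somatic consensus filter keeps a call only when every rule holds:
support by at least two callers within the variant class's caller set
(SNVs: Strelka/VarScan/MuTect; indels: Strelka/VarScan/Pindel), tumor depth
>= 14 and normal depth >= 8, tumor VAF >= 0.05 and normal VAF <= 0.02,
indel length < 100 bp, exonic, and not (dbSNP and not COSMIC). The germline
filter requires alt depth >= 5 and alt fraction >= 20% in both tumor and
normal, a coding-region location, and population frequency < 0.05%. All
boundary comparisons are implemented exactly as printed (see docs); every
threshold is configurable.

Depth and VAF are defined on ref+alt counts (bam-readcount-style biallelic
convention); a sample with zero depth has undefined VAF and the record
fails with reason "no-depth" rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNV_CALLERS = frozenset({"strelka", "varscan", "mutect"})
INDEL_CALLERS = frozenset({"strelka", "varscan", "pindel"})


@dataclass
class SomaticThresholds:
    min_callers: int = 2
    min_tumor_depth: int = 14
    min_normal_depth: int = 8
    min_tumor_vaf: float = 0.05
    max_normal_vaf: float = 0.02
    max_indel_length: int = 100  # strict: indel length must be < this
    require_exonic: bool = True
    exclude_dbsnp_not_cosmic: bool = True
    snv_callers: frozenset = field(default_factory=lambda: SNV_CALLERS)
    indel_callers: frozenset = field(default_factory=lambda: INDEL_CALLERS)


@dataclass
class GermlineThresholds:
    min_alt_depth: int = 5
    min_alt_fraction: float = 0.20
    max_pop_af: float = 0.0005  # strict: pop_af must be < this
    require_coding: bool = True


def _vaf(alt: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """alt/(ref+alt), NaN where depth is zero."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(depth > 0, alt / np.where(depth > 0, depth, 1), np.nan)


def _ensure_class(records: pd.DataFrame) -> pd.Series:
    if "variant_class" in records.columns:
        return records["variant_class"]
    return pd.Series(
        np.where(
            (records["ref"].str.len() == 1) & (records["alt"].str.len() == 1),
            "SNV",
            "indel",
        ),
        index=records.index,
    )


def filter_somatic(
    records: pd.DataFrame, thresholds: SomaticThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the consensus somatic filter.

    Returns ``(pass_table, fail_table)``; the fail table carries a
    ``reasons`` column listing every violated rule for each record, so
    pass and fail partition the input exactly.
    """
    th = thresholds or SomaticThresholds()
    if records.empty:
        empty = records.copy()
        return empty, empty.assign(reasons=pd.Series(dtype=object))

    vclass = _ensure_class(records)
    td = (records["tumor_ref_count"] + records["tumor_alt_count"]).to_numpy()
    nd = (records["normal_ref_count"] + records["normal_alt_count"]).to_numpy()
    tvaf = _vaf(records["tumor_alt_count"].to_numpy(), td)
    nvaf = _vaf(records["normal_alt_count"].to_numpy(), nd)
    is_indel = (vclass == "indel").to_numpy()
    indel_len = (records["ref"].str.len() - records["alt"].str.len()).abs().to_numpy()

    n_support = np.array(
        [
            len(set(c) & (th.indel_callers if ind else th.snv_callers))
            for c, ind in zip(records["callers"], is_indel)
        ]
    )

    checks: list[tuple[str, np.ndarray]] = [
        ("no-depth", (td == 0) | (nd == 0)),
        ("caller-support", n_support < th.min_callers),
        ("tumor-depth", td < th.min_tumor_depth),
        ("normal-depth", nd < th.min_normal_depth),
        ("tumor-vaf", ~(tvaf >= th.min_tumor_vaf)),  # NaN fails
        ("normal-vaf", ~(nvaf <= th.max_normal_vaf)),
        ("indel-length", is_indel & (indel_len >= th.max_indel_length)),
    ]
    if th.require_exonic:
        checks.append(("not-exonic", ~records["exonic"].to_numpy(dtype=bool)))
    if th.exclude_dbsnp_not_cosmic:
        checks.append(
            (
                "dbsnp-not-cosmic",
                records["in_dbsnp"].to_numpy(dtype=bool)
                & ~records["in_cosmic"].to_numpy(dtype=bool),
            )
        )
    return _partition(records, checks)


def filter_germline(
    records: pd.DataFrame, thresholds: GermlineThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the germline depth/AF/population-frequency filter."""
    th = thresholds or GermlineThresholds()
    if records.empty:
        empty = records.copy()
        return empty, empty.assign(reasons=pd.Series(dtype=object))

    td = (records["tumor_ref_count"] + records["tumor_alt_count"]).to_numpy()
    nd = (records["normal_ref_count"] + records["normal_alt_count"]).to_numpy()
    taf = _vaf(records["tumor_alt_count"].to_numpy(), td)
    naf = _vaf(records["normal_alt_count"].to_numpy(), nd)
    talt = records["tumor_alt_count"].to_numpy()
    nalt = records["normal_alt_count"].to_numpy()

    checks: list[tuple[str, np.ndarray]] = [
        ("no-depth", (td == 0) | (nd == 0)),
        ("allelic-depth", (talt < th.min_alt_depth) | (nalt < th.min_alt_depth)),
        (
            "allele-frequency",
            ~((taf >= th.min_alt_fraction) & (naf >= th.min_alt_fraction)),
        ),
        ("population-frequency", records["pop_af"].to_numpy() >= th.max_pop_af),
    ]
    if th.require_coding:
        checks.append(
            ("non-coding", ~records["in_coding_region"].to_numpy(dtype=bool))
        )
    return _partition(records, checks)


def _partition(
    records: pd.DataFrame, checks: list[tuple[str, np.ndarray]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    fail_any = np.zeros(len(records), dtype=bool)
    reasons: list[list[str]] = [[] for _ in range(len(records))]
    for name, bad in checks:
        fail_any |= bad
        for i in np.flatnonzero(bad):
            reasons[i].append(name)
    passed = records.loc[~fail_any].copy()
    failed = records.loc[fail_any].copy()
    failed["reasons"] = [";".join(reasons[i]) for i in np.flatnonzero(fail_any)]
    return passed, failed


def hotspot_vafs(readcounts: pd.DataFrame) -> pd.DataFrame:
    """Per-locus VAFs from base readcounts at hotspot positions.

    Input rows carry (chrom, pos, ref_base, A, C, G, T). For each
    non-reference base with count > 0, VAF = count(base) /
    (count(base) + count(ref_base)). A locus with zero total coverage is
    reported once with a missing VAF and ``no_coverage=True``.
    """
    bases = ["A", "C", "G", "T"]
    rows = []
    for rec in readcounts.itertuples(index=False):
        ref = rec.ref_base
        if ref not in bases:
            raise ValueError(f"ref_base must be one of {bases}, got {ref!r}")
        counts = {b: int(getattr(rec, b)) for b in bases}
        if any(v < 0 for v in counts.values()):
            raise ValueError(f"negative base count at {rec.chrom}:{rec.pos}")
        total = sum(counts.values())
        if total == 0:
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "alt_base": None,
                    "vaf": np.nan,
                    "no_coverage": True,
                }
            )
            continue
        for b in bases:
            if b == ref or counts[b] == 0:
                continue
            denom = counts[b] + counts[ref]
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "alt_base": b,
                    "vaf": counts[b] / denom,
                    "no_coverage": False,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "alt_base", "vaf", "no_coverage"]
    )
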