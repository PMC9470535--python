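"""Seeded synthetic-cohort generator.

Emulates the statistical structure of a multi-sample pancreatic tumor atlas:
cell groups (tumor, PanIN, ADM, normal ductal, acinar) with planted
per-group mutation-mapping rates, UMI-duplicated reads with a per-duplicate
allele-flip error, multi-caller variant call sets spanning every filter
branch, negative-binomial expression with cluster-specific gene programs,
and gene-level CNV matrices carrying arm-level shifts and deep focal
events. Every output is a deterministic function of the seed, and ground
truth is recorded alongside so downstream modules can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io

DRIVER_GENES = ["KRAS", "CDKN2A", "SMAD4", "TP53"]
#: real chromosome arms of the driver genes (plus the planted focal-gain gene)
DRIVER_ARMS = {
    "KRAS": ("12", "p"),
    "CDKN2A": ("9", "p"),
    "SMAD4": ("18", "q"),
    "TP53": ("17", "p"),
    "AKT2": ("19", "q"),
}

BASES = ["A", "C", "G", "T"]


def _default_groups() -> dict[str, int]:
    return {
        "tumor": 800,
        "panin": 600,
        "adm": 400,
        "normal_duct": 600,
        "acinar": 600,
    }


def _default_rates() -> dict[str, float]:
    # planted mapping rates: tumor > panin > background groups
    return {
        "tumor": 0.30,
        "panin": 0.15,
        "adm": 0.01,
        "normal_duct": 0.01,
        "acinar": 0.01,
    }


def _default_arm_events() -> list[tuple[str, float, tuple[str, ...]]]:
    return [("8q", 0.5, ("tumor",)), ("18q", -0.5, ("tumor",))]


def _default_deep_events() -> list[tuple[str, float, str, float]]:
    # (gene, planted value, group, fraction of that group's cells)
    return [("AKT2", 2.5, "tumor", 0.15), ("CDKN2A", 0.05, "tumor", 0.15)]


def _default_samples() -> list[tuple[str, float, float]]:
    # S2 sits 10 mm from S1 (spatially separable); S3 only 2 mm away
    return [("S1", 0.0, 0.0), ("S2", 10.0, 0.0), ("S3", 2.0, 0.0)]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; the seed fully determines output.

    Parameters
    ----------
    n_cells_per_group
        Cohort composition across the five emulated populations.
    mapping_rate
        Per-cell probability that a variant-supporting molecule is observed
        at a given site, per group.
    background_ref_rate
        Poisson rate of reference molecules per cell per site, so total
        coverage is nonzero for the enrichment statistic.
    umi_dup_rate
        Probability a molecule yields a further duplicate read (geometric
        tail: reads per molecule = 1 + Geometric(umi_dup_rate)).
    allele_error_rate
        Per-read probability that the observed allele flips to one of the
        other two states, creating within-UMI conflicts for consensus.
    program_size, program_log2_fc
        Size and effect of each cluster-specific expression program.
    nb_dispersion
        Negative-binomial size parameter of expression counts.
    arm_events
        (arm, shift, groups) copy-number shifts applied at arm level.
    deep_gene_events
        (gene, value, group, cell fraction) focal deep events feeding the
        hierarchical cell labeler.
    samples
        (sample_id, x_mm, y_mm) physical section coordinates.
    """

    seed: int = 0
    n_cells_per_group: Mapping[str, int] = field(default_factory=_default_groups)
    mapping_rate: Mapping[str, float] = field(default_factory=_default_rates)
    background_ref_rate: float = 0.5
    umi_dup_rate: float = 0.3
    allele_error_rate: float = 0.01
    n_variants: int = 20
    n_genes: int = 1000
    n_clusters: int = 4
    program_size: int = 50
    program_log2_fc: float = 2.0
    program_gene_sets: Mapping[str, tuple[Sequence[str], float]] | None = None
    nb_dispersion: float = 2.0
    mean_counts_per_cell: float = 2500.0
    n_qc_violators: int = 6
    cnv_noise_sd: float = 0.05
    arm_events: list = field(default_factory=_default_arm_events)
    deep_gene_events: list = field(default_factory=_default_deep_events)
    samples: list = field(default_factory=_default_samples)
    n_call_records: int = 1000
    n_gene_sets: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.umi_dup_rate < 1.0:
            raise ValueError(
                f"umi_dup_rate must be in [0, 1), got {self.umi_dup_rate}"
            )
        if not 0.0 <= self.allele_error_rate <= 1.0:
            raise ValueError(
                f"allele_error_rate must be in [0, 1], got {self.allele_error_rate}"
            )
        for g, p in self.mapping_rate.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mapping_rate[{g}]={p} outside [0, 1]")
        for g, n in self.n_cells_per_group.items():
            if n <= 0:
                raise ValueError(f"n_cells_per_group[{g}] must be positive")
        if self.background_ref_rate < 0:
            raise ValueError("background_ref_rate must be non-negative")
        if min(self.n_variants, self.n_genes, self.n_clusters) <= 0:
            raise ValueError("counts must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream for each sub-simulator."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted truth recorded by the generator, for exact validation."""

    cells: pd.DataFrame  # barcode, group, sample_id, cluster
    variants: pd.DataFrame  # chrom, pos, ref, alt, gene
    molecule_counts: pd.DataFrame | None = None  # cell, site, ref/alt molecules
    callset_truth: pd.DataFrame | None = None  # per-record intended pass/fail
    program_genes: dict | None = None  # cluster -> planted gene list
    arm_shifts: list | None = None
    deep_events: pd.DataFrame | None = None
    qc_fail_barcodes: list | None = None

    def to_json(self) -> dict:
        out = {
            "cells": self.cells.to_dict(orient="list"),
            "variants": self.variants.to_dict(orient="list"),
        }
        if self.molecule_counts is not None:
            out["molecule_counts"] = self.molecule_counts.to_dict(orient="list")
        if self.callset_truth is not None:
            out["callset_truth"] = self.callset_truth.assign(
                callers=self.callset_truth["callers"].map(
                    lambda s: ",".join(sorted(s))
                )
            ).to_dict(orient="list")
        if self.program_genes is not None:
            out["program_genes"] = {k: list(v) for k, v in self.program_genes.items()}
        if self.arm_shifts is not None:
            out["arm_shifts"] = [list(e) for e in self.arm_shifts]
        if self.deep_events is not None:
            out["deep_events"] = self.deep_events.to_dict(orient="list")
        if self.qc_fail_barcodes is not None:
            out["qc_fail_barcodes"] = list(self.qc_fail_barcodes)
        return out


# ---------------------------------------------------------------------------
# shared cohort structure


def gene_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene annotation: drivers, mito genes, filler genes.

    Genes get synthetic lengths and a chromosome-arm assignment; the driver
    genes sit on their real arms so planted arm events land where the
    analysis expects them.
    """
    n = cfg.n_genes
    names = DRIVER_GENES + ["AKT2"]
    names += [f"MT-G{i}" for i in range(1, 11)]
    names += [f"GENE{i:04d}" for i in range(1, n - len(names) + 1)]
    names = names[:n]
    chroms, arms = [], []
    arm_cycle = [(str(c), a) for c in range(1, 23) for a in ("p", "q")]
    j = 0
    for g in names:
        if g in DRIVER_ARMS:
            c, a = DRIVER_ARMS[g]
        else:
            c, a = arm_cycle[j % len(arm_cycle)]
            j += 1
        chroms.append(c)
        arms.append(a)
    rng = np.random.default_rng(20_220_801)  # gene annotation is seed-independent
    lengths = rng.integers(500, 10_000, size=n)
    bands = [f"{c}{a}{(i % 3) + 1}{(i % 4) + 1}" for i, (c, a) in enumerate(zip(chroms, arms))]
    return pd.DataFrame(
        {
            "gene": names,
            "chrom": chroms,
            "arm": arms,
            "band": bands,
            "length_bp": lengths,
            "mito_flag": [g.startswith("MT-") for g in names],
        }
    ).set_index("gene", drop=False)


def cell_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Deterministic cell roster shared by all sub-simulators.

    Tumor cells split into ``n_clusters`` subclusters; cluster c0 is planted
    as spatially distinct (96% from the far sample S2), cluster c1 draws 96%
    from the near sample S3 (fails the distance rule), the rest mix samples.
    Non-tumor cells carry their group name as cluster and mix samples.
    """
    rng = cfg.rng(1)
    sample_ids = [s[0] for s in cfg.samples]
    rows = []
    idx = 0
    for group, n in cfg.n_cells_per_group.items():
        for _ in range(n):
            rows.append((f"CB{idx:06d}", group))
            idx += 1
    df = pd.DataFrame(rows, columns=["barcode", "group"])

    clusters = np.empty(len(df), dtype=object)
    samples = np.empty(len(df), dtype=object)
    tumor_mask = (df["group"] == "tumor").to_numpy()
    tumor_idx = np.flatnonzero(tumor_mask)
    assign = tumor_idx % cfg.n_clusters  # balanced subclusters
    for k in range(cfg.n_clusters):
        members = tumor_idx[assign == k]
        clusters[members] = f"c{k}"
        if k == 0 and len(sample_ids) >= 2:
            dominant, others = sample_ids[1], sample_ids
        elif k == 1 and len(sample_ids) >= 3:
            dominant, others = sample_ids[2], sample_ids
        else:
            dominant, others = None, sample_ids
        if dominant is None:
            samples[members] = rng.choice(others, size=len(members))
        else:
            pick = rng.random(len(members)) < 0.96
            samples[members] = np.where(
                pick, dominant, rng.choice(others, size=len(members))
            )
    non_tumor = np.flatnonzero(~tumor_mask)
    clusters[non_tumor] = df["group"].to_numpy()[non_tumor]
    samples[non_tumor] = rng.choice(sample_ids, size=len(non_tumor))
    df["cluster"] = clusters
    df["sample_id"] = samples
    return df.set_index("barcode", drop=False)


def variant_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Variant site list; the first four sites hit the driver genes."""
    genes = gene_table(cfg)
    rng = cfg.rng(2)
    names = list(genes.index)
    target_genes = DRIVER_GENES[: cfg.n_variants]
    pool = [g for g in names if g not in DRIVER_GENES and not g.startswith("MT-")]
    extra = rng.choice(pool, size=max(0, cfg.n_variants - len(target_genes)), replace=False)
    target_genes = target_genes + list(extra)
    refs = rng.choice(BASES, size=cfg.n_variants)
    alts = [
        BASES[(BASES.index(r) + int(k)) % 4]
        for r, k in zip(refs, rng.integers(1, 4, size=cfg.n_variants))
    ]
    return pd.DataFrame(
        {
            "chrom": [genes.loc[g, "chrom"] for g in target_genes],
            "pos": 1_000_000 + 10_000 * np.arange(cfg.n_variants),
            "ref": refs,
            "alt": alts,
            "gene": target_genes,
        }
    )


# ---------------------------------------------------------------------------
# read observations


def simulate_read_observations(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the barcoded, UMI-tagged allele-observation table.

    Per cell and variant site, one alt molecule is drawn with probability
    ``mapping_rate[group]`` and reference molecules with Poisson rate
    ``background_ref_rate``. Each molecule is emitted as
    ``1 + Geometric(umi_dup_rate)`` duplicate reads sharing (cell, UMI);
    each read independently flips its observed allele with probability
    ``allele_error_rate`` (uniformly to one of the other two states),
    exercising the consensus rule downstream.
    """
    cells = cell_table(cfg)
    variants = variant_table(cfg)
    rng = cfg.rng(3)

    n_cells, n_sites = len(cells), len(variants)
    rates = cells["group"].map(cfg.mapping_rate).to_numpy(dtype=float)
    alt_mol = (rng.random((n_cells, n_sites)) < rates[:, None]).astype(np.int64)
    ref_mol = rng.poisson(cfg.background_ref_rate, size=(n_cells, n_sites))

    truth = pd.DataFrame(
        {
            "cell_barcode": np.repeat(cells["barcode"].to_numpy(), n_sites),
            "site_index": np.tile(np.arange(n_sites), n_cells),
            "alt_molecules": alt_mol.ravel(),
            "ref_molecules": ref_mol.ravel(),
        }
    )

    # expand molecules to reads
    n_mol_per = alt_mol.ravel() + ref_mol.ravel()
    pair_idx = np.repeat(np.arange(n_cells * n_sites), n_mol_per)
    total_mol = int(n_mol_per.sum())
    # within each (cell, site) pair the first alt_molecules are alt
    offsets = np.concatenate(([0], np.cumsum(n_mol_per)[:-1]))
    within = np.arange(total_mol) - offsets[pair_idx]
    is_alt = within < alt_mol.ravel()[pair_idx]

    # reads per molecule = 1 + Geometric(umi_dup_rate):
    # P(k reads) = umi_dup_rate^(k-1) * (1 - umi_dup_rate), k >= 1
    if cfg.umi_dup_rate > 0:
        n_reads = rng.geometric(1.0 - cfg.umi_dup_rate, size=total_mol)
    else:
        n_reads = np.ones(total_mol, dtype=np.int64)
    mol_idx = np.repeat(np.arange(total_mol), n_reads)
    true_allele = np.where(is_alt, "alt", "ref").astype(object)[mol_idx]

    n_total_reads = len(mol_idx)
    flip = rng.random(n_total_reads) < cfg.allele_error_rate
    flip_pick = rng.integers(0, 2, size=n_total_reads)
    others = {"ref": ["alt", "other"], "alt": ["ref", "other"]}
    observed = true_allele.copy()
    if flip.any():
        fl = np.flatnonzero(flip)
        observed[fl] = [others[true_allele[i]][flip_pick[i]] for i in fl]

    cell_idx = pair_idx[mol_idx] // n_sites
    site_idx = pair_idx[mol_idx] % n_sites
    obs = pd.DataFrame(
        {
            "chrom": variants["chrom"].to_numpy()[site_idx],
            "pos": variants["pos"].to_numpy()[site_idx],
            "ref": variants["ref"].to_numpy()[site_idx],
            "alt": variants["alt"].to_numpy()[site_idx],
            "cell_barcode": cells["barcode"].to_numpy()[cell_idx],
            "umi": np.char.add("U", np.char.zfill(mol_idx.astype(str), 8)),
            "observed_allele": observed,
        }
    )
    gt = GroundTruth(cells=cells.reset_index(drop=True), variants=variants,
                     molecule_counts=truth)
    return obs, gt


# ---------------------------------------------------------------------------
# multi-caller call sets

_SNV_CALLERS = ["strelka", "varscan", "mutect"]
_INDEL_CALLERS = ["strelka", "varscan", "pindel"]


def _intended_somatic_pass(rec: dict) -> bool:
    """Generator-side statement of the consensus-filter truth.

    Deliberately written as a plain if-chain, independent of the vectorized
    filter engine it validates.
    """
    td = rec["tumor_ref_count"] + rec["tumor_alt_count"]
    nd = rec["normal_ref_count"] + rec["normal_alt_count"]
    if td == 0 or nd == 0:
        return False
    allowed = _SNV_CALLERS if rec["variant_class"] == "SNV" else _INDEL_CALLERS
    if len(set(rec["callers"]) & set(allowed)) < 2:
        return False
    if td < 14 or nd < 8:
        return False
    if rec["tumor_alt_count"] / td < 0.05:
        return False
    if rec["normal_alt_count"] / nd > 0.02:
        return False
    if rec["variant_class"] == "indel":
        if abs(len(rec["ref"]) - len(rec["alt"])) >= 100:
            return False
    if not rec["exonic"]:
        return False
    if rec["in_dbsnp"] and not rec["in_cosmic"]:
        return False
    return True


def simulate_callsets(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random multi-caller somatic call records spanning every filter branch.

    Returns (records, truth) where truth carries the intended pass/fail per
    record. Depths, VAFs, caller support, indel lengths and annotation flags
    straddle every threshold, and a deterministic block of exact boundary
    records (VAF 0.05/0.02, depths 14/13 and 8/7, indel lengths 99/100) is
    appended so the inclusive/strict comparisons are always exercised.
    """
    rng = cfg.rng(4)
    n = cfg.n_call_records
    rows: list[dict] = []
    for i in range(n):
        is_indel = rng.random() < 0.3
        vclass = "indel" if is_indel else "SNV"
        allowed = _INDEL_CALLERS if is_indel else _SNV_CALLERS
        k = int(rng.integers(1, 4))
        callers = frozenset(rng.choice(allowed, size=k, replace=False))
        td = int(rng.integers(0, 41))
        nd = int(rng.integers(0, 31))
        talt = int(rng.integers(0, td + 1)) if td else 0
        # normal alt concentrated near zero so both VAF branches occur
        nalt = int(min(nd, rng.geometric(0.7) - 1)) if nd else 0
        ref = "A"
        if is_indel:
            ln = int(rng.integers(1, 121))
            alt = "A" + "C" * ln
        else:
            alt = "G"
        rows.append(
            {
                "chrom": str(rng.integers(1, 23)),
                "pos": int(rng.integers(1, 10_000_000)),
                "ref": ref,
                "alt": alt,
                "variant_class": vclass,
                "callers": callers,
                "tumor_ref_count": td - talt,
                "tumor_alt_count": talt,
                "normal_ref_count": nd - nalt,
                "normal_alt_count": nalt,
                "exonic": bool(rng.random() < 0.8),
                "in_dbsnp": bool(rng.random() < 0.3),
                "in_cosmic": bool(rng.random() < 0.3),
            }
        )

    def _boundary(vclass, callers, tref, talt, nref, nalt, alt="G", **kw):
        base = {
            "chrom": "1",
            "pos": 1000 + len(rows),
            "ref": "A",
            "alt": alt,
            "variant_class": vclass,
            "callers": frozenset(callers),
            "tumor_ref_count": tref,
            "tumor_alt_count": talt,
            "normal_ref_count": nref,
            "normal_alt_count": nalt,
            "exonic": True,
            "in_dbsnp": False,
            "in_cosmic": True,
        }
        base.update(kw)
        rows.append(base)

    # exact boundaries: tumor VAF 0.05 (pass) / just below (fail)
    _boundary("SNV", ["strelka", "varscan"], 19, 1, 10, 0)
    _boundary("SNV", ["strelka", "varscan"], 39, 1, 10, 0)  # VAF 0.025 < 0.05
    # normal VAF exactly 0.02 (pass) / above (fail)
    _boundary("SNV", ["strelka", "mutect"], 10, 10, 49, 1)
    _boundary("SNV", ["strelka", "mutect"], 10, 10, 29, 1)  # 1/30 > 0.02
    # depth boundaries 14/13 and 8/7
    _boundary("SNV", ["varscan", "mutect"], 7, 7, 8, 0)
    _boundary("SNV", ["varscan", "mutect"], 6, 7, 8, 0)
    _boundary("SNV", ["varscan", "mutect"], 10, 10, 8, 0)
    _boundary("SNV", ["varscan", "mutect"], 10, 10, 7, 0)
    # indel length 99 (pass) / 100 (fail)
    _boundary("indel", ["strelka", "pindel"], 10, 10, 10, 0, alt="A" + "C" * 99)
    _boundary("indel", ["strelka", "pindel"], 10, 10, 10, 0, alt="A" + "C" * 100)
    # single caller only
    _boundary("SNV", ["mutect"], 10, 10, 10, 0)
    # dbSNP without COSMIC
    _boundary("SNV", ["strelka", "varscan"], 10, 10, 10, 0,
              in_dbsnp=True, in_cosmic=False)
    # zero-depth normal
    _boundary("SNV", ["strelka", "varscan"], 10, 10, 0, 0)

    records = pd.DataFrame(rows)
    records["record_id"] = np.arange(len(records))
    truth = records[["record_id", "callers"]].copy()
    truth["intended_pass"] = [
        _intended_somatic_pass(r) for r in records.to_dict(orient="records")
    ]
    return records, truth


def _intended_germline_pass(rec: dict) -> bool:
    td = rec["tumor_ref_count"] + rec["tumor_alt_count"]
    nd = rec["normal_ref_count"] + rec["normal_alt_count"]
    if td == 0 or nd == 0:
        return False
    if rec["tumor_alt_count"] < 5 or rec["normal_alt_count"] < 5:
        return False
    if rec["tumor_alt_count"] / td < 0.20 or rec["normal_alt_count"] / nd < 0.20:
        return False
    if not rec["in_coding_region"]:
        return False
    if rec["pop_af"] >= 0.0005:
        return False
    return True


def simulate_germline_callsets(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random germline call records straddling the depth/AF/gnomAD filters."""
    rng = cfg.rng(5)
    n = cfg.n_call_records
    td = rng.integers(0, 60, size=n)
    nd = rng.integers(0, 60, size=n)
    talt = np.minimum(td, rng.integers(0, 30, size=n))
    nalt = np.minimum(nd, rng.integers(0, 30, size=n))
    pop = rng.choice(
        [0.0, 0.0001, 0.0004, 0.0005, 0.0006, 0.01], size=n,
        p=[0.4, 0.15, 0.15, 0.1, 0.1, 0.1],
    )
    records = pd.DataFrame(
        {
            "chrom": rng.integers(1, 23, size=n).astype(str),
            "pos": rng.integers(1, 10_000_000, size=n),
            "ref": rng.choice(BASES, size=n),
            "alt": rng.choice(BASES, size=n),
            "tumor_ref_count": td - talt,
            "tumor_alt_count": talt,
            "normal_ref_count": nd - nalt,
            "normal_alt_count": nalt,
            "pop_af": pop,
            "in_coding_region": rng.random(n) < 0.8,
        }
    )
    records["record_id"] = np.arange(n)
    truth = records[["record_id"]].copy()
    truth["intended_pass"] = [
        _intended_germline_pass(r) for r in records.to_dict(orient="records")
    ]
    return records, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(cfg: SimulationConfig):
    """Negative-binomial cells x genes counts with planted cluster programs.

    Returns an AnnData: counts in ``X``, cell metadata (sample_id, group,
    cluster) in ``obs``, gene metadata (mito_flag, length_bp, chrom/arm) in
    ``var``. Each tumor subcluster upshifts its program genes by
    ``program_log2_fc``. A handful of extra cells violating the QC
    thresholds (low depth, few genes, extreme UMIs, high mito fraction) are
    appended and recorded in ground truth.
    """
    import anndata as ad
    import scipy.sparse as sp

    genes = gene_table(cfg)
    cells = cell_table(cfg)
    rng = cfg.rng(6)

    n_cells, n_genes = len(cells), len(genes)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base *= cfg.mean_counts_per_cell / base.sum()
    depth = rng.lognormal(mean=0.0, sigma=0.25, size=n_cells)

    programs = _program_genes(cfg, genes)
    fc = np.ones((n_cells, n_genes))
    gene_pos = {g: i for i, g in enumerate(genes.index)}
    for cluster, (members, log2fc) in programs.items():
        rows = (cells["cluster"] == cluster).to_numpy()
        cols = [gene_pos[g] for g in members]
        fc[np.ix_(rows, cols)] = 2.0 ** log2fc

    mu = depth[:, None] * base[None, :] * fc
    size = cfg.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(np.int32)

    # QC violators appended at the end with recognizable barcodes
    qc_rows, qc_meta = [], []
    sample_ids = [s[0] for s in cfg.samples]
    mito_cols = genes["mito_flag"].to_numpy()
    for i in range(cfg.n_qc_violators):
        kind = ["low-counts", "few-genes", "high-umis", "high-mito"][i % 4]
        row = np.zeros(n_genes, dtype=np.int32)
        if kind == "low-counts":
            cols = rng.choice(n_genes, size=100, replace=False)
            row[cols] = 1  # 100 counts < 300
        elif kind == "few-genes":
            cols = rng.choice(n_genes, size=50, replace=False)
            row[cols] = 40  # 2000 counts but only 50 genes
        elif kind == "high-umis":
            # ~15000 UMIs regardless of gene count, > 10000 ceiling
            row[:] = rng.poisson(15_000.0 / n_genes, size=n_genes)
        else:
            row[:] = rng.poisson(2.0, size=n_genes)
            row[mito_cols] += rng.poisson(150, size=int(mito_cols.sum()))
        qc_rows.append(row)
        qc_meta.append(
            {
                "barcode": f"QC{i:04d}",
                "group": "tumor",
                "cluster": "c0",
                "sample_id": sample_ids[0],
            }
        )

    obs = pd.concat([cells.reset_index(drop=True), pd.DataFrame(qc_meta)],
                    ignore_index=True)
    X = np.vstack([counts] + [r[None, :] for r in qc_rows])
    adata = ad.AnnData(
        X=sp.csr_matrix(X),
        obs=obs.set_index("barcode", drop=False),
        var=genes[["gene", "chrom", "arm", "band", "length_bp", "mito_flag"]].copy(),
    )
    adata.uns["ground_truth_programs"] = {
        k: list(v[0]) for k, v in programs.items()
    }
    adata.uns["qc_fail_barcodes"] = [m["barcode"] for m in qc_meta]
    return adata


def _program_genes(cfg: SimulationConfig, genes: pd.DataFrame):
    """Planted per-cluster programs: disjoint blocks of filler genes."""
    if cfg.program_gene_sets is not None:
        return {k: (list(v[0]), float(v[1])) for k, v in cfg.program_gene_sets.items()}
    pool = [g for g in genes.index if g.startswith("GENE")]
    out = {}
    for k in range(cfg.n_clusters):
        block = pool[k * cfg.program_size : (k + 1) * cfg.program_size]
        out[f"c{k}"] = (block, cfg.program_log2_fc)
    return out


def make_gene_sets(cfg: SimulationConfig) -> dict[str, list[str]]:
    """Hallmark-like collection: one set per planted program plus filler sets."""
    genes = gene_table(cfg)
    programs = _program_genes(cfg, genes)
    rng = cfg.rng(7)
    sets: dict[str, list[str]] = {}
    for cluster, (members, _) in programs.items():
        sets[f"HALLMARK_SYNTH_PROGRAM_{cluster.upper()}"] = list(members)
    pool = [g for g in genes.index if not g.startswith("MT-")]
    i = 0
    while len(sets) < cfg.n_gene_sets:
        name = f"HALLMARK_SYNTH_RANDOM_{i:02d}"
        sets[name] = sorted(rng.choice(pool, size=cfg.program_size, replace=False))
        i += 1
    return sets


# ---------------------------------------------------------------------------
# CNV


def simulate_cnv_matrix(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell gene-level copy-number-like matrix (neutral = 1.0).

    Arm events shift every gene on the arm in the designated groups; deep
    focal events overwrite single genes in a random subset of a group's
    cells. Returns (matrix cells x genes, deep-event truth table).
    """
    genes = gene_table(cfg)
    cells = cell_table(cfg)
    rng = cfg.rng(8)

    arm_of_gene = (genes["chrom"] + genes["arm"]).to_numpy()
    vals = 1.0 + rng.normal(0.0, cfg.cnv_noise_sd, size=(len(cells), len(genes)))
    group_arr = cells["group"].to_numpy()
    for arm, shift, groups in cfg.arm_events:
        gmask = arm_of_gene == arm
        if not gmask.any():
            raise ValueError(f"arm event references arm {arm} with no mapped genes")
        cmask = np.isin(group_arr, list(groups))
        vals[np.ix_(cmask, gmask)] += shift

    deep_rows = []
    gene_pos = {g: i for i, g in enumerate(genes.index)}
    for gene, value, group, frac in cfg.deep_gene_events:
        members = np.flatnonzero(group_arr == group)
        chosen = rng.choice(members, size=max(1, int(round(frac * len(members)))),
                            replace=False)
        vals[chosen, gene_pos[gene]] = value + rng.normal(
            0.0, cfg.cnv_noise_sd, size=len(chosen)
        )
        for c in chosen:
            deep_rows.append({"cell_barcode": cells["barcode"].iloc[c],
                              "gene": gene, "planted_value": value})

    mat = pd.DataFrame(vals, index=cells["barcode"], columns=genes.index)
    return mat, pd.DataFrame(deep_rows)


def band_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Gene -> (chrom, band) table consumed by the arm mapper."""
    genes = gene_table(cfg)
    return genes[["gene", "chrom", "band"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort writer


def simulate_cohort(cfg: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Generate and write every pipeline input under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    obs, gt = simulate_read_observations(cfg)
    _io.write_observations(obs, outdir / "read_observations.tsv")

    records, call_truth = simulate_callsets(cfg)
    _io.write_vcf(records, outdir / "somatic_calls.vcf")
    gt.callset_truth = call_truth

    # the mapped variant list itself (all sites are real planted variants)
    variants = gt.variants.copy()
    variants["variant_class"] = "SNV"
    variants["callers"] = [frozenset(["strelka", "varscan"])] * len(variants)
    variants["tumor_ref_count"] = 50
    variants["tumor_alt_count"] = 25
    variants["normal_ref_count"] = 40
    variants["normal_alt_count"] = 0
    variants["exonic"] = True
    variants["in_dbsnp"] = False
    variants["in_cosmic"] = True
    _io.write_vcf(variants, outdir / "mapped_variants.vcf")

    adata = simulate_expression(cfg)
    _io.write_expression(adata, outdir / "expression")
    adata.obs[["barcode", "sample_id", "group", "cluster"]].to_csv(
        outdir / "cell_meta.tsv", sep="\t", index=False
    )
    gt.program_genes = adata.uns["ground_truth_programs"]
    gt.qc_fail_barcodes = adata.uns["qc_fail_barcodes"]

    cnv, deep = simulate_cnv_matrix(cfg)
    cnv.round(4).to_csv(outdir / "cnv_gene_matrix.tsv", sep="\t")
    gt.deep_events = deep
    gt.arm_shifts = [list(e) for e in cfg.arm_events]
    band_table(cfg).to_csv(outdir / "gene_bands.tsv", sep="\t", index=False)

    _io.write_gmt(make_gene_sets(cfg), outdir / "gene_sets.gmt")
    pd.DataFrame(cfg.samples, columns=["sample_id", "x_mm", "y_mm"]).to_csv(
        outdir / "sample_geography.tsv", sep="\t", index=False
    )
    _io.write_json(gt.to_json(), outdir / "ground_truth.json")
    return gt
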