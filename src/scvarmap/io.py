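"""Readers and writers for the pipeline's on-disk formats.

Variant call sets travel as biallelic VCF (read back through pysam); read
observations, per-cell counts, CNV matrices and band tables travel as TSV;
expression matrices as MTX triplets with barcode/feature sidecars (via
anndata); gene sets as GMT.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import pandas as pd
import pysam

#: columns of the read-observation table, one row per read
OBS_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "cell_barcode",
    "umi",
    "observed_allele",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Callers supporting this variant">
##INFO=<ID=TVAF,Number=1,Type=Float,Description="Tumor variant allele fraction">
##INFO=<ID=NVAF,Number=1,Type=Float,Description="Normal variant allele fraction">
##INFO=<ID=TDEPTH,Number=1,Type=Integer,Description="Tumor depth (ref+alt)">
##INFO=<ID=NDEPTH,Number=1,Type=Integer,Description="Normal depth (ref+alt)">
##INFO=<ID=TALT,Number=1,Type=Integer,Description="Tumor alt read count">
##INFO=<ID=NALT,Number=1,Type=Integer,Description="Normal alt read count">
##INFO=<ID=EXONIC,Number=1,Type=Integer,Description="1 if variant is exonic">
##INFO=<ID=DBSNP,Number=1,Type=Integer,Description="1 if variant is in dbSNP">
##INFO=<ID=COSMIC,Number=1,Type=Integer,Description="1 if variant is in COSMIC">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(records: pd.DataFrame, path: str | Path) -> None:
    """Write somatic call records as a biallelic VCF.

    Expects the SomaticCallRecord columns (chrom, pos, ref, alt, callers,
    tumor_ref_count, tumor_alt_count, normal_ref_count, normal_alt_count,
    exonic, in_dbsnp, in_cosmic) plus an optional ``gene`` column.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        for row in records.itertuples(index=False):
            td = row.tumor_ref_count + row.tumor_alt_count
            nd = row.normal_ref_count + row.normal_alt_count
            tvaf = row.tumor_alt_count / td if td else 0.0
            nvaf = row.normal_alt_count / nd if nd else 0.0
            callers = ",".join(sorted(row.callers))
            info = (
                f"CALLERS={callers if callers else '.'};"
                f"TVAF={tvaf:.6g};NVAF={nvaf:.6g};"
                f"TDEPTH={td};NDEPTH={nd};"
                f"TALT={row.tumor_alt_count};NALT={row.normal_alt_count};"
                f"EXONIC={int(row.exonic)};DBSNP={int(row.in_dbsnp)};"
                f"COSMIC={int(row.in_cosmic)}"
            )
            gene = getattr(row, "gene", None)
            if gene:
                info += f";GENE={gene}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t{info}\n"
            )


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a biallelic VCF into a SomaticCallRecord table.

    Multi-allelic rows are rejected: the filter engine operates on
    pre-split biallelic records only. Alt counts are taken from the
    TALT/NALT keys when present, otherwise reconstructed as
    round(VAF * depth).
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; "
                    "split to biallelic records first"
                )
            info = rec.info
            td = int(info.get("TDEPTH", 0))
            nd = int(info.get("NDEPTH", 0))
            if "TALT" in info:
                talt = int(info["TALT"])
            else:
                talt = int(round(float(info.get("TVAF", 0.0)) * td))
            if "NALT" in info:
                nalt = int(info["NALT"])
            else:
                nalt = int(round(float(info.get("NVAF", 0.0)) * nd))
            callers = info.get("CALLERS", ())
            if isinstance(callers, str):
                callers = (callers,)
            callers = frozenset(c for c in callers if c and c != ".")
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "callers": callers,
                    "tumor_ref_count": td - talt,
                    "tumor_alt_count": talt,
                    "normal_ref_count": nd - nalt,
                    "normal_alt_count": nalt,
                    "exonic": bool(int(info.get("EXONIC", 0))),
                    "in_dbsnp": bool(int(info.get("DBSNP", 0))),
                    "in_cosmic": bool(int(info.get("COSMIC", 0))),
                    "gene": info.get("GENE", None),
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["variant_class"] = [
            "SNV" if len(r) == 1 and len(a) == 1 else "indel"
            for r, a in zip(df["ref"], df["alt"])
        ]
    return df


def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    obs.to_csv(path, sep="\t", index=False, columns=OBS_COLUMNS)


def read_observations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "umi": str})


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def write_expression(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as an MTX triplet with barcode/feature TSV sidecars."""
    import scipy.io
    import scipy.sparse as sp

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    adata.obs.to_csv(outdir / "barcodes.tsv", sep="\t")
    adata.var.to_csv(outdir / "features.tsv", sep="\t")


def read_expression(outdir: str | Path) -> ad.AnnData:
    import scipy.io

    outdir = Path(outdir)
    X = scipy.io.mmread(str(outdir / "matrix.mtx")).T.tocsr()
    obs = pd.read_csv(outdir / "barcodes.tsv", sep="\t", index_col=0)
    var = pd.read_csv(outdir / "features.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_json(obj, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=1, default=str)
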