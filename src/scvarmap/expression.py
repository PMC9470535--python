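"""Cell QC, differential expression, gene-set enrichment and pathway scoring.

The droplet QC removes a barcode when it violates any of: total transcript
counts < 300, genes expressed < 200, UMIs < 1,000, genes > 10,000,
UMIs > 10,000, or mitochondrial fraction strictly > 10%. In droplet data
total transcript counts and UMIs are the same quantity; both thresholds are
applied independently as stated, so the effective lower bound is 1,000.

Cluster markers use a two-sided Wilcoxon rank-sum test (tie-corrected
normal approximation) on the log-normalized layer, prefiltered by detection
fraction (min.pct; the "subcluster" profile additionally requires a
detection-fraction difference, min.diff.pct) and positive log fold change,
with Bonferroni adjustment over all genes and an adjusted-p < 0.05 cut.
Over-representation against a gene-set collection is the upper-tail
hypergeometric test with BH adjustment. Pathway scores average the
normalized expression of the genes contributing to significant enrichments
of a pathway (union over clusters), per cluster, then center and scale each
pathway across clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class QCThresholds:
    min_counts: int = 300
    min_genes: int = 200
    min_umis: int = 1000
    max_genes: int = 10_000
    max_umis: int = 10_000
    max_pct_mito: float = 0.10  # strict: fraction must be <= this to keep


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def cell_qc_metrics(adata: ad.AnnData, mito_key: str = "mito_flag") -> pd.DataFrame:
    """Per-cell totals, expressed-gene counts and mitochondrial fraction."""
    X = adata.X
    total = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    if mito_key in adata.var:
        mito = np.asarray(
            X[:, adata.var[mito_key].to_numpy(dtype=bool)].sum(axis=1)
        ).ravel()
    else:
        mito = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(total > 0, mito / np.where(total > 0, total, 1), 0.0)
    return pd.DataFrame(
        {
            "total_counts": total,
            "n_genes": n_genes,
            "n_umis": total,
            "pct_mito": pct_mito,
        },
        index=adata.obs_names,
    )


def qc_filter_cells(
    adata: ad.AnnData,
    thresholds: QCThresholds | None = None,
    mito_key: str = "mito_flag",
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove barcodes violating any QC rule; report per-cell reasons."""
    th = thresholds or QCThresholds()
    m = cell_qc_metrics(adata, mito_key=mito_key)
    checks = [
        ("min-counts", m["total_counts"] < th.min_counts),
        ("min-genes", m["n_genes"] < th.min_genes),
        ("min-umis", m["n_umis"] < th.min_umis),
        ("max-genes", m["n_genes"] > th.max_genes),
        ("max-umis", m["n_umis"] > th.max_umis),
        ("max-mito", m["pct_mito"] > th.max_pct_mito),
    ]
    reasons = pd.Series([""] * adata.n_obs, index=adata.obs_names)
    removed = np.zeros(adata.n_obs, dtype=bool)
    for name, bad in checks:
        bad = bad.to_numpy()
        removed |= bad
        reasons[bad] = reasons[bad].where(reasons[bad] == "", reasons[bad] + ";") + name
    report = m.copy()
    report["removed"] = removed
    report["reasons"] = reasons
    return adata[~removed].copy(), report


def normalize_log(adata: ad.AnnData, layer: str = "lognorm") -> ad.AnnData:
    """Depth-scale each cell to the median depth, then log1p.

    A deterministic library-size normalization standing in for heavier
    variance-stabilizing transforms; all-zero cells stay all-zero.
    """
    X = adata.X.astype(float)
    total = np.asarray(X.sum(axis=1)).ravel()
    target = float(np.median(total[total > 0])) if (total > 0).any() else 1.0
    scale = np.where(total > 0, target / np.where(total > 0, total, 1), 0.0)
    if sp.issparse(X):
        Xn = sp.diags(scale) @ X
        Xn.data = np.log1p(Xn.data)
    else:
        Xn = np.log1p(X * scale[:, None])
    adata.layers[layer] = Xn
    return adata


# ---------------------------------------------------------------------------
# differential expression

DEG_PROFILES = {
    "global": {"min_pct": 0.25, "min_diff_pct": 0.0},
    "subcluster": {"min_pct": 0.10, "min_diff_pct": 0.10},
}


def find_degs(
    adata: ad.AnnData,
    cluster_key: str = "cluster",
    profile: str = "global",
    layer: str = "lognorm",
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    filtered: bool = True,
) -> pd.DataFrame:
    """Positive cluster markers by Wilcoxon rank-sum, one cluster vs rest.

    Genes enter the test when max(pct_in, pct_out) >= min.pct, (subcluster
    profile) pct_in - pct_out >= min.diff.pct, and log fold change > 0.
    log_fc is the natural-log ratio of (mean expm1(normalized) + 1).
    P-values are Bonferroni-adjusted over all genes in the matrix; the
    returned table keeps p_adj < alpha, sorted by descending log_fc.
    """
    if profile not in DEG_PROFILES:
        raise ValueError(f"profile must be one of {sorted(DEG_PROFILES)}")
    prof = DEG_PROFILES[profile]
    if layer not in adata.layers:
        raise ValueError(f"layer {layer!r} missing; run normalize_log first")
    Xn = _dense(adata.layers[layer])
    Xc = _dense(adata.X)
    clusters = adata.obs[cluster_key]
    genes = np.asarray(adata.var_names)
    n_genes_total = adata.n_vars

    out = []
    for cl in pd.unique(clusters):
        inside = (clusters == cl).to_numpy()
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        if n_in < 2 or n_out < 2:
            warnings.warn(f"cluster {cl!r} has <2 cells on one side; skipped")
            continue
        pct_in = (Xc[inside] > 0).mean(axis=0)
        pct_out = (Xc[~inside] > 0).mean(axis=0)
        mean_in = np.expm1(Xn[inside]).mean(axis=0)
        mean_out = np.expm1(Xn[~inside]).mean(axis=0)
        log_fc = np.log((mean_in + 1.0) / (mean_out + 1.0))

        keep = np.maximum(pct_in, pct_out) >= prof["min_pct"]
        if prof["min_diff_pct"] > 0:
            keep &= (pct_in - pct_out) >= prof["min_diff_pct"]
        keep &= log_fc > 0
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        stat = sps.mannwhitneyu(
            Xn[np.ix_(inside, idx)],
            Xn[np.ix_(~inside, idx)],
            alternative="two-sided",
            method="asymptotic",
            axis=0,
        )
        p = np.atleast_1d(stat.pvalue)
        if adjust == "bonferroni":
            p_adj = np.minimum(p * n_genes_total, 1.0)
        elif adjust == "fdr_bh":
            p_adj = multipletests(p, method="fdr_bh")[1]
        else:
            raise ValueError("adjust must be 'bonferroni' or 'fdr_bh'")
        out.append(
            pd.DataFrame(
                {
                    "cluster": cl,
                    "gene": genes[idx],
                    "log_fc": log_fc[idx],
                    "pct_in": pct_in[idx],
                    "pct_out": pct_out[idx],
                    "p": p,
                    "p_adj": p_adj,
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["cluster", "gene", "log_fc", "pct_in", "pct_out", "p", "p_adj"]
        )
    degs = pd.concat(out, ignore_index=True)
    if filtered:
        degs = degs[degs["p_adj"] < alpha]
    return degs.sort_values(
        ["cluster", "log_fc"], ascending=[True, False]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# over-representation and pathway scoring


def ora_hypergeometric(
    deg_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation against each gene set.

    With a universe of M genes of which K belong to the set, and a DEG list
    of size n drawn from the universe, the enrichment p is
    P(overlap >= k) = hypergeom.sf(k-1, M, K, n). q is BH across sets.
    Genes outside the universe are dropped (with a warning).
    """
    uni = set(universe)
    degs = [g for g in dict.fromkeys(deg_genes) if g in uni]
    dropped = len(set(deg_genes)) - len(degs)
    if dropped:
        warnings.warn(f"{dropped} DEG(s) outside the universe were dropped")
    if not degs:
        return pd.DataFrame(
            columns=["pathway", "overlap", "set_size", "deg_size", "universe_size",
                     "p", "p_adj", "overlap_genes"]
        )
    M, n = len(uni), len(degs)
    deg_set = set(degs)
    rows = []
    for name, members in gene_sets.items():
        in_uni = set(members) & uni
        K = len(in_uni)
        overlap = sorted(deg_set & in_uni)
        k = len(overlap)
        p = float(sps.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(
            {
                "pathway": name,
                "overlap": k,
                "set_size": K,
                "deg_size": n,
                "universe_size": M,
                "p": p,
                "overlap_genes": overlap,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df[["pathway", "overlap", "set_size", "deg_size", "universe_size",
               "p", "p_adj", "overlap_genes"]]


def detection_universe(adata: ad.AnnData, min_frac: float = 0.001) -> list[str]:
    """Genes detected in more than ``min_frac`` of cells."""
    frac = np.asarray((adata.X > 0).mean(axis=0)).ravel()
    return list(np.asarray(adata.var_names)[frac > min_frac])


def pathway_scores(
    adata: ad.AnnData,
    enrichments: Mapping[str, pd.DataFrame],
    cluster_key: str = "cluster",
    layer: str = "lognorm",
    alpha: float = 0.05,
    min_cluster_frac: float = 0.001,
    top_k: int | None = None,
    member_mode: str = "overlap-union",
    gene_sets: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Pathways x clusters centered/scaled mean-expression scores.

    ``enrichments`` maps cluster -> ORA table for that cluster's DEGs. A
    pathway's member genes are the union over clusters of the overlap genes
    from its significant (p_adj < alpha) enrichments (or the whole set when
    ``member_mode="whole-set"``, requiring ``gene_sets``). Clusters holding
    fewer than ``min_cluster_frac`` of all cells are excluded first.
    score(pathway, cluster) = mean normalized expression of member genes
    over the cluster's cells; each pathway row is then centered and scaled
    (sample sd, n-1) across clusters. Constant rows become zeros and are
    flagged. Pathways are ranked by the number of clusters in which they
    were significant; ``top_k`` keeps the most recurrent ones.
    """
    if member_mode not in ("overlap-union", "whole-set"):
        raise ValueError("member_mode must be 'overlap-union' or 'whole-set'")
    if member_mode == "whole-set" and gene_sets is None:
        raise ValueError("whole-set mode requires gene_sets")

    clusters = adata.obs[cluster_key]
    sizes = clusters.value_counts()
    kept_clusters = sizes[sizes / adata.n_obs >= min_cluster_frac].index.tolist()

    members: dict[str, set] = {}
    occurrence: dict[str, int] = {}
    for cl, table in enrichments.items():
        if cl not in kept_clusters or table.empty:
            continue
        sig = table[table["p_adj"] < alpha]
        for r in sig.itertuples(index=False):
            occurrence[r.pathway] = occurrence.get(r.pathway, 0) + 1
            add = (
                set(gene_sets[r.pathway])
                if member_mode == "whole-set"
                else set(r.overlap_genes)
            )
            members.setdefault(r.pathway, set()).update(add)

    ranked = sorted(occurrence, key=lambda p: (-occurrence[p], p))
    if top_k is not None:
        ranked = ranked[:top_k]
    if not ranked:
        return pd.DataFrame(), {}

    Xn = _dense(adata.layers[layer])
    var_index = {g: i for i, g in enumerate(adata.var_names)}
    raw = np.zeros((len(ranked), len(kept_clusters)))
    member_lists: dict[str, list[str]] = {}
    for i, pw in enumerate(ranked):
        genes = sorted(g for g in members[pw] if g in var_index)
        member_lists[pw] = genes
        cols = [var_index[g] for g in genes]
        for j, cl in enumerate(kept_clusters):
            cells = (clusters == cl).to_numpy()
            raw[i, j] = Xn[np.ix_(cells, cols)].mean() if cols else 0.0

    mean = raw.mean(axis=1, keepdims=True)
    if raw.shape[1] < 2:  # a single cluster has no spread to scale by
        sd = np.zeros_like(mean)
    else:
        sd = raw.std(axis=1, ddof=1, keepdims=True)
    constant = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(sd > 0, (raw - mean) / np.where(sd > 0, sd, 1), 0.0)
    df = pd.DataFrame(scores, index=ranked, columns=kept_clusters)
    df.attrs["constant_rows"] = [p for p, c in zip(ranked, constant) if c]
    df.attrs["occurrence"] = {p: occurrence[p] for p in ranked}
    return df, member_lists


# ---------------------------------------------------------------------------
# spatial rule and bulk transform


def spatial_distinct_clusters(
    cell_meta: pd.DataFrame,
    geography: pd.DataFrame,
    cluster_key: str = "cluster",
    sample_key: str = "sample_id",
    min_fraction: float = 0.95,
    min_distance_mm: float = 6.0,
) -> pd.DataFrame:
    """Flag clusters whose cells overwhelmingly come from one distant sample.

    A cluster is spatially distinct iff >= ``min_fraction`` of its cells
    originate from a single sample AND that sample lies >=
    ``min_distance_mm`` from every other sample contributing cells to the
    dataset. Both boundaries are inclusive.
    """
    geo = geography.set_index("sample_id") if "sample_id" in geography else geography
    missing = set(cell_meta[sample_key].unique()) - set(geo.index)
    if missing:
        raise ValueError(f"samples missing coordinates: {sorted(missing)}")
    coords = geo[["x_mm", "y_mm"]].astype(float)

    rows = []
    all_samples = cell_meta[sample_key].unique()
    for cl, sub in cell_meta.groupby(cluster_key, observed=True):
        frac = sub[sample_key].value_counts(normalize=True)
        dominant = frac.index[0]
        top = float(frac.iloc[0])
        others = [s for s in all_samples if s != dominant]
        if others:
            d = np.sqrt(
                ((coords.loc[others] - coords.loc[dominant]) ** 2).sum(axis=1)
            )
            far_enough = bool((d >= min_distance_mm).all())
            min_d = float(d.min())
        else:
            far_enough, min_d = True, np.inf
        rows.append(
            {
                "cluster": cl,
                "dominant_sample": dominant,
                "fraction": top,
                "min_distance_mm": min_d,
                "distinct": top >= min_fraction and far_enough,
            }
        )
    return pd.DataFrame(rows)


def fpkm_uq_transform(
    counts: pd.DataFrame,
    lengths: pd.Series,
    protein_coding: pd.Series | None = None,
) -> pd.DataFrame:
    """Upper-quartile FPKM with log2(x+1), genes x samples.

    FPKM-UQ(g, s) = count(g, s) * 1e9 / (length(g) * UQ(s)) where UQ(s) is
    the 75th percentile of the sample's counts over protein-coding genes
    with count > 0 (all genes treated as coding when no flag is given).
    Samples whose UQ is zero are reported unusable.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[lengths.isna() | (lengths <= 0)]
        raise ValueError(f"genes with missing/non-positive length: {list(bad)[:5]}")
    coding = (
        protein_coding.reindex(counts.index).fillna(False).to_numpy(dtype=bool)
        if protein_coding is not None
        else np.ones(len(counts), dtype=bool)
    )
    out = {}
    for s in counts.columns:
        col = counts[s].to_numpy(dtype=float)
        expressed = coding & (col > 0)
        uq = np.percentile(col[expressed], 75) if expressed.any() else 0.0
        if uq == 0:
            raise ValueError(f"sample {s!r} has zero upper quartile; unusable")
        out[s] = np.log2(col * 1e9 / (lengths.to_numpy() * uq) + 1.0)
    return pd.DataFrame(out, index=counts.index)
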