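"""QC, normalization, DEGs, ORA, pathway scores, spatial rule, FPKM-UQ."""

import dataclasses
import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scvarmap import (
    QCThresholds,
    find_degs,
    fpkm_uq_transform,
    normalize_log,
    ora_hypergeometric,
    pathway_scores,
    qc_filter_cells,
    simulate_expression,
    spatial_distinct_clusters,
)
from scvarmap.expression import cell_qc_metrics, detection_universe


def _adata(X, mito=None, **obs_cols):
    X = np.asarray(X)
    var = pd.DataFrame(index=[f"g{i}" for i in range(X.shape[1])])
    var["mito_flag"] = mito if mito is not None else False
    obs = pd.DataFrame(obs_cols, index=[f"c{i}" for i in range(X.shape[0])])
    return ad.AnnData(X=sp.csr_matrix(X.astype(float)), obs=obs, var=var)


# ---------------------------------------------------------------------------
# QC


def test_qc_removes_low_gene_cell():
    X = np.zeros((2, 300))
    X[0, :150] = 10  # 150 genes, 1500 counts -> min-genes only
    X[1, :250] = 10  # 250 genes, 2500 counts -> kept
    kept, report = qc_filter_cells(_adata(X), QCThresholds(min_umis=1000))
    assert kept.n_obs == 1
    assert report.loc["c0", "removed"]
    assert "min-genes" in report.loc["c0", "reasons"]
    assert "min-counts" not in report.loc["c0", "reasons"]


def test_qc_keeps_cell_passing_all_thresholds():
    X = np.zeros((1, 600))
    X[0, :500] = 3  # 500 genes, 1500 UMIs
    X[0, 0] = 3 + 135  # mito bumps to ~9%
    mito = np.zeros(600, dtype=bool)
    mito[0] = True
    a = _adata(X, mito=mito)
    m = cell_qc_metrics(a)
    assert m["pct_mito"].iloc[0] < 0.10
    kept, _ = qc_filter_cells(a)
    assert kept.n_obs == 1


def test_qc_mito_boundary_is_strict():
    X = np.zeros((1, 400))
    X[0, :400] = 5  # 2000 counts, 400 genes
    mito = np.zeros(400, dtype=bool)
    mito[:40] = True  # exactly 10% of counts
    kept, report = qc_filter_cells(_adata(X, mito=mito))
    assert kept.n_obs == 1  # strictly > 10% removes; exactly 10% kept
    X2 = X.copy()
    X2[0, 0] += 1  # nudge above 10%
    kept2, report2 = qc_filter_cells(_adata(X2, mito=mito))
    assert kept2.n_obs == 0
    assert "max-mito" in report2["reasons"].iloc[0]


def test_qc_extreme_umi_cells_removed():
    X = np.zeros((2, 1200))
    X[0] = 10  # 12000 UMIs > 10000 (and >10000 genes is impossible here)
    X[1, :500] = 4
    kept, report = qc_filter_cells(_adata(X))
    assert kept.n_obs == 1
    assert "max-umis" in report["reasons"].iloc[0]


def test_qc_partition_and_reason_consistency(small_cfg):
    adata = simulate_expression(small_cfg)
    kept, report = qc_filter_cells(adata)
    assert kept.n_obs + int(report["removed"].sum()) == adata.n_obs
    # planted violators are all removed
    assert report.loc[adata.uns["qc_fail_barcodes"], "removed"].all()
    # reasons reproduce the decision
    assert (report["removed"] == (report["reasons"] != "")).all()


# ---------------------------------------------------------------------------
# normalization


def test_normalize_zero_cell_stays_zero():
    X = np.array([[0, 0, 0], [1, 2, 3]])
    a = normalize_log(_adata(X))
    assert np.allclose(a.layers["lognorm"].toarray()[0], 0.0)


def test_normalize_depth_invariance():
    X = np.array([[1.0, 2, 3], [2, 4, 6], [5, 0, 5]])
    a = normalize_log(_adata(X))
    L = a.layers["lognorm"].toarray()
    assert np.allclose(L[0], L[1])


def test_normalize_matches_direct_recomputation():
    rng = np.random.default_rng(0)
    X = rng.poisson(3.0, size=(20, 30)).astype(float)
    a = normalize_log(_adata(X))
    totals = X.sum(axis=1)
    target = np.median(totals[totals > 0])
    expected = np.log1p(X / totals[:, None] * target)
    assert np.allclose(a.layers["lognorm"].toarray(), expected)


# ---------------------------------------------------------------------------
# DEGs


def _clustered_adata(n_per=60, n_genes=120, n_prog=20, log2fc=2.0, seed=0):
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(0.5, 0.5, size=n_genes)
    X1 = rng.poisson(mu, size=(n_per, n_genes))
    mu2 = mu.copy()
    mu2[:n_prog] *= 2.0 ** log2fc
    X2 = rng.poisson(mu2, size=(n_per, n_genes))
    a = _adata(np.vstack([X1, X2]),
               cluster=["rest"] * n_per + ["prog"] * n_per)
    return normalize_log(a)


def test_planted_program_recovered():
    a = _clustered_adata()
    degs = find_degs(a, profile="global")
    hits = set(degs.loc[degs["cluster"] == "prog", "gene"])
    planted = {f"g{i}" for i in range(20)}
    assert len(hits & planted) >= 0.9 * len(planted)
    # sorted by descending fold change within cluster
    lf = degs.loc[degs["cluster"] == "prog", "log_fc"].to_numpy()
    assert (np.diff(lf) <= 1e-12).all()


def test_min_pct_excludes_rare_genes():
    rng = np.random.default_rng(1)
    X = np.zeros((100, 10))
    X[:, 1:] = rng.poisson(3.0, size=(100, 9))
    X[:3, 0] = 50  # detected in 3% of cells on both sides
    a = _adata(X, cluster=["a"] * 50 + ["b"] * 50)
    a = normalize_log(a)
    degs = find_degs(a, profile="global", filtered=False)
    assert "g0" not in set(degs["gene"])


def test_min_diff_pct_applies_in_subcluster_profile():
    X = np.zeros((100, 4))
    X[:, 0] = 5  # detected everywhere: pct diff 0
    X[50:, 1] = 5  # only in cluster b
    X[:, 2:] = 3
    a = _adata(X, cluster=["a"] * 50 + ["b"] * 50)
    a = normalize_log(a)
    degs = find_degs(a, profile="subcluster", filtered=False)
    genes_b = set(degs.loc[degs["cluster"] == "b", "gene"])
    assert "g1" in genes_b
    assert "g0" not in genes_b


def test_wilcoxon_matches_hand_rank_sum():
    """Tie-corrected normal approximation recomputed from rank sums."""
    from scipy.stats import rankdata

    a = _clustered_adata(n_per=40, n_genes=30, seed=2)
    degs = find_degs(a, profile="global", filtered=False)
    Xn = a.layers["lognorm"].toarray()
    inside = (a.obs["cluster"] == "prog").to_numpy()
    n1, n2 = inside.sum(), (~inside).sum()
    for row in degs[degs["cluster"] == "prog"].itertuples(index=False):
        j = list(a.var_names).index(row.gene)
        x = Xn[:, j]
        ranks = rankdata(x)
        r1 = ranks[inside].sum()
        u1 = r1 - n1 * (n1 + 1) / 2
        mu = n1 * n2 / 2
        _, tie_counts = np.unique(x, return_counts=True)
        tie_term = (tie_counts ** 3 - tie_counts).sum()
        n = n1 + n2
        sigma = math.sqrt(n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1))))
        from scipy.stats import norm

        z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / sigma  # continuity-corrected
        p = 2 * norm.sf(abs(z))
        assert row.p == pytest.approx(min(p, 1.0), abs=1e-8)


def test_permuted_labels_yield_no_calls():
    rng = np.random.default_rng(4)
    a = _clustered_adata(seed=5)
    labels = a.obs["cluster"].to_numpy().copy()
    rng.shuffle(labels)
    a.obs["cluster"] = labels
    degs = find_degs(a, profile="global")
    assert len(degs) <= 2  # Bonferroni leaves essentially nothing under the null


def test_tiny_cluster_skipped_with_warning():
    X = np.random.default_rng(0).poisson(2.0, size=(21, 10))
    a = _adata(X, cluster=["a"] * 20 + ["b"])
    a = normalize_log(a)
    with pytest.warns(UserWarning, match="<2 cells"):
        degs = find_degs(a, profile="global", filtered=False)
    assert set(degs["cluster"]) <= {"a"}


# ---------------------------------------------------------------------------
# ORA


def test_ora_exact_toy_example():
    universe = [f"g{i}" for i in range(10)]
    sets = {"S": universe[:5]}
    out = ora_hypergeometric(universe[:4], sets, universe)
    # P(X >= 4) drawing 4 from 10 with 5 marked = C(5,4)C(5,0)/C(10,4)
    assert out.iloc[0]["p"] == pytest.approx(5 / 210, abs=1e-15)
    assert out.iloc[0]["overlap"] == 4


def test_ora_zero_overlap_never_significant():
    universe = [f"g{i}" for i in range(20)]
    sets = {"S": universe[:5]}
    out = ora_hypergeometric(universe[10:14], sets, universe)
    assert out.iloc[0]["overlap"] == 0
    assert out.iloc[0]["p"] == pytest.approx(1.0)


def test_ora_deg_equals_universe_forces_p_one():
    universe = [f"g{i}" for i in range(12)]
    sets = {"A": universe[:3], "B": universe[3:9]}
    out = ora_hypergeometric(universe, sets, universe)
    assert np.allclose(out["p"], 1.0)


def test_ora_genes_outside_universe_dropped_with_warning():
    universe = [f"g{i}" for i in range(10)]
    sets = {"S": universe[:5]}
    with pytest.warns(UserWarning, match="outside the universe"):
        out = ora_hypergeometric(["g0", "nope"], sets, universe)
    assert out.iloc[0]["deg_size"] == 1


def test_ora_matches_exact_enumeration_small_grid():
    """math.comb enumeration oracle over a grid of small universes."""
    for M in range(2, 13):
        universe = [f"g{i}" for i in range(M)]
        for n_deg in range(1, M + 1):
            degs = universe[:n_deg]
            sets = {}
            for K in range(1, M + 1):
                # set with maximal overlap given sizes
                sets[f"S{K}"] = universe[:K]
            out = ora_hypergeometric(degs, sets, universe).set_index("pathway")
            for K in range(1, M + 1):
                k = min(K, n_deg)
                exact = sum(
                    math.comb(K, j) * math.comb(M - K, n_deg - j)
                    for j in range(k, min(K, n_deg) + 1)
                ) / math.comb(M, n_deg)
                assert out.loc[f"S{K}", "p"] == pytest.approx(exact, abs=1e-12)


# ---------------------------------------------------------------------------
# pathway scores


def _enrichment_row(pathway, genes, p_adj=0.01):
    return pd.DataFrame(
        [{"pathway": pathway, "overlap": len(genes), "p": p_adj, "p_adj": p_adj,
          "overlap_genes": list(genes)}]
    )


def test_pathway_score_center_scale_arithmetic():
    # cluster means 1, 2, 3 -> scores (-1, 0, 1)
    X = np.zeros((3, 2))
    X[:, 0] = [math.expm1(1), math.expm1(2), math.expm1(3)]
    a = _adata(X, cluster=["c1", "c2", "c3"])
    a.layers["lognorm"] = sp.csr_matrix(np.log1p(X))
    enr = {"c3": _enrichment_row("P", ["g0"])}
    scores, members = pathway_scores(a, enr, min_cluster_frac=0.0)
    assert np.allclose(scores.loc["P", ["c1", "c2", "c3"]], [-1.0, 0.0, 1.0])
    assert members["P"] == ["g0"]


def test_pathway_constant_row_is_zero_and_flagged():
    X = np.ones((4, 1))
    a = _adata(X, cluster=["c1", "c1", "c2", "c2"])
    a.layers["lognorm"] = sp.csr_matrix(X)
    enr = {"c1": _enrichment_row("P", ["g0"])}
    scores, _ = pathway_scores(a, enr, min_cluster_frac=0.0)
    assert np.allclose(scores.loc["P"], 0.0)
    assert "P" in scores.attrs["constant_rows"]


def test_pathway_rows_centered_scaled(small_cfg):
    adata = simulate_expression(small_cfg)
    kept, _ = qc_filter_cells(adata)
    kept = normalize_log(kept)
    tumor = kept[kept.obs["group"] == "tumor"].copy()
    from scvarmap.simulate import make_gene_sets

    degs = find_degs(tumor, profile="subcluster")
    sets = make_gene_sets(small_cfg)
    universe = detection_universe(tumor)
    enr = {
        cl: ora_hypergeometric(
            degs.loc[degs["cluster"] == cl, "gene"].tolist(), sets, universe
        )
        for cl in tumor.obs["cluster"].unique()
    }
    scores, _ = pathway_scores(tumor, enr)
    vals = scores.to_numpy()
    nonconst = [p for p in scores.index if p not in scores.attrs["constant_rows"]]
    assert len(nonconst) >= small_cfg.n_clusters
    sub = scores.loc[nonconst].to_numpy()
    assert np.abs(sub.mean(axis=1)).max() < 1e-9
    assert np.abs(sub.std(axis=1, ddof=1) - 1).max() < 1e-9
    # planted programs peak in their own cluster
    for k in range(small_cfg.n_clusters):
        name = f"HALLMARK_SYNTH_PROGRAM_C{k}"
        assert scores.loc[name].idxmax() == f"c{k}"


def test_small_clusters_excluded_from_scores():
    X = np.random.default_rng(0).poisson(2.0, size=(101, 5)).astype(float)
    a = _adata(X, cluster=["big"] * 100 + ["tiny"])
    a.layers["lognorm"] = sp.csr_matrix(np.log1p(X))
    enr = {"big": _enrichment_row("P", ["g0"]),
           "tiny": _enrichment_row("P", ["g1"])}
    scores, _ = pathway_scores(a, enr, min_cluster_frac=0.05)
    assert "tiny" not in scores.columns


# ---------------------------------------------------------------------------
# spatial rule


GEO = pd.DataFrame(
    {"sample_id": ["P1", "P2"], "x_mm": [0.0, 6.0], "y_mm": [0.0, 0.0]}
)


def _meta(n_p1, n_p2):
    return pd.DataFrame(
        {
            "cluster": ["t0"] * (n_p1 + n_p2),
            "sample_id": ["P1"] * n_p1 + ["P2"] * n_p2,
        }
    )


def test_spatial_distinct_boundaries_inclusive():
    out = spatial_distinct_clusters(_meta(96, 4), GEO)
    assert out.iloc[0]["distinct"]  # 96% and exactly 6 mm


def test_spatial_fraction_below_threshold():
    out = spatial_distinct_clusters(_meta(94, 6), GEO)
    assert not out.iloc[0]["distinct"]


def test_spatial_distance_below_threshold():
    geo = GEO.assign(x_mm=[0.0, 2.0])
    out = spatial_distinct_clusters(_meta(98, 2), geo)
    assert not out.iloc[0]["distinct"]


def test_spatial_missing_sample_errors():
    with pytest.raises(ValueError, match="P2"):
        spatial_distinct_clusters(_meta(9, 1), GEO.iloc[[0]])


# ---------------------------------------------------------------------------
# FPKM-UQ


def test_fpkm_uq_direct_arithmetic():
    counts = pd.DataFrame({"s1": [100, 1000]}, index=["gA", "gB"])
    lengths = pd.Series([1000, 4000], index=["gA", "gB"])
    out = fpkm_uq_transform(counts, lengths)
    # UQ = 75th percentile of expressed counts (100, 1000) = 775
    uq = np.percentile([100, 1000], 75)
    expected = math.log2(100 * 1e9 / (1000 * uq) + 1)
    assert out.loc["gA", "s1"] == pytest.approx(expected)


def test_fpkm_uq_zero_count_gives_zero():
    counts = pd.DataFrame({"s1": [0, 10]}, index=["gA", "gB"])
    lengths = pd.Series([1000, 1000], index=["gA", "gB"])
    out = fpkm_uq_transform(counts, lengths)
    assert out.loc["gA", "s1"] == 0.0


def test_fpkm_uq_scale_invariance():
    counts = pd.DataFrame({"s1": [5, 10, 20]}, index=["gA", "gB", "gC"])
    lengths = pd.Series([1000, 2000, 500], index=counts.index)
    a = fpkm_uq_transform(counts, lengths)
    b = fpkm_uq_transform(counts * 2, lengths)
    pd.testing.assert_frame_equal(a, b)


def test_fpkm_uq_unusable_sample():
    counts = pd.DataFrame({"s1": [0, 0]}, index=["gA", "gB"])
    lengths = pd.Series([1000, 1000], index=counts.index)
    with pytest.raises(ValueError, match="unusable"):
        fpkm_uq_transform(counts, lengths)


def test_fpkm_uq_uses_coding_genes_for_uq():
    counts = pd.DataFrame({"s1": [100, 10_000]}, index=["gA", "gB"])
    lengths = pd.Series([1000, 1000], index=counts.index)
    coding = pd.Series([True, False], index=counts.index)
    out = fpkm_uq_transform(counts, lengths, protein_coding=coding)
    expected = math.log2(100 * 1e9 / (1000 * 100) + 1)  # UQ over {100} = 100
    assert out.loc["gA", "s1"] == pytest.approx(expected)
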