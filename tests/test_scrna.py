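"""QC, normalization, variable genes, rank-sum markers and gene-set refinement."""

import itertools

import numpy as np
import pytest
import anndata as ad
import pandas as pd
import scipy.sparse as sp

from trcaf import simulate_scrna
from trcaf.scrna import (
    GeneSet,
    find_variable_genes,
    normalize,
    prrx1_refine,
    qc_filter,
    specificity_filter,
    wilcoxon_markers,
)
from tests.conftest import small_scrna_cfg


def _adata_from_counts(counts, genes=None, obs=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    a = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        var=pd.DataFrame(index=genes),
        obs=obs if obs is not None else pd.DataFrame(
            index=[f"c{i}" for i in range(counts.shape[0])]
        ),
    )
    return a


# ---------------------------------------------------------------------------
# exact rank-sum oracle (enumeration over all group assignments)
# ---------------------------------------------------------------------------

def oracle_ranksum_exact_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:n1].sum()
    stats = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    stats = np.asarray(stats, float)
    cdf = (stats <= obs + 1e-9).mean()
    sf = (stats >= obs - 1e-9).mean()
    return min(1.0, 2 * min(cdf, sf))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_thresholds_follow_quoted_rules():
    # cells: genes detected / umi / mito fraction
    n_genes = 7000
    counts = np.zeros((4, n_genes), dtype=int)
    counts[0, :150] = 10            # 150 genes -> removed (needs >200)
    counts[1, :3000] = 2            # 3000 genes, 6000 umi, no mito -> kept
    counts[2, :250] = 5             # 1250 umi but 30% mito -> removed
    counts[3, :250] = 3             # 750 umi -> removed (needs >1000)
    genes = [f"g{i}" for i in range(n_genes - 1)] + ["MT-1"]
    a = _adata_from_counts(counts, genes=genes)
    a.X[2, n_genes - 1] = 536       # ~30% of this cell's counts
    from trcaf.scrna import ensure_qc
    ensure_qc(a)
    kept = qc_filter(a)
    assert list(kept.obs_names) == ["c1"]
    assert kept.n_vars == n_genes   # gene roster unchanged


def test_qc_is_idempotent(norm_adata):
    once = qc_filter(norm_adata)
    twice = qc_filter(once)
    assert list(once.obs_names) == list(twice.obs_names)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_matches_direct_arithmetic():
    a = _adata_from_counts([[1, 1, 2]])
    n = normalize(a, scale_factor=1e4)
    vals = n.layers["lognorm"].toarray()[0]
    assert np.allclose(vals, np.log1p([2500, 2500, 5000]))


def test_normalize_scale_invariance_and_roundtrip():
    a = _adata_from_counts([[1, 2, 3, 0]])
    b = _adata_from_counts([[2, 4, 6, 0]])
    na, nb = normalize(a), normalize(b)
    assert np.allclose(na.layers["lognorm"].toarray(),
                       nb.layers["lognorm"].toarray())
    # expm1 of a normalized cell sums to the scale factor
    assert np.expm1(na.layers["lognorm"].toarray()).sum() == pytest.approx(1e4)


def test_normalize_drops_zero_total_cells_with_warning():
    a = _adata_from_counts([[1, 1], [0, 0]])
    with pytest.warns(UserWarning):
        n = normalize(a)
    assert n.n_obs == 1


# ---------------------------------------------------------------------------
# variable genes
# ---------------------------------------------------------------------------

def test_variable_genes_window_and_dispersion_rules(norm_adata):
    hv = find_variable_genes(norm_adata, n_top=50)
    assert 0 < len(hv) <= 50
    # constant nonzero gene has zero dispersion and is never selected
    a = norm_adata.copy()
    X = a.layers["lognorm"].toarray()
    X[:, 0] = 1.0
    a.layers["lognorm"] = sp.csr_matrix(X)
    hv2 = find_variable_genes(a, n_top=50)
    assert a.var_names[0] not in hv2


def test_variable_genes_prefer_planted_bimodal_gene(norm_adata):
    # cluster-structured marker genes are bimodal across clusters and should
    # be selected at a much higher rate than matched constant-rate fillers
    hv = set(find_variable_genes(norm_adata, n_top=60))
    modules = {g for mod in small_scrna_cfg().marker_modules.values() for g in mod}
    fillers = set(norm_adata.var_names) - modules
    rate_mod = len(hv & modules) / len(modules)
    rate_fill = len(hv & fillers) / len(fillers)
    assert rate_mod > 2 * rate_fill


def test_variable_genes_agree_with_scanpy_reference(norm_adata):
    scanpy = pytest.importorskip("scanpy")
    hv = find_variable_genes(norm_adata, n_top=60)
    a = norm_adata.copy()
    a.X = a.layers["lognorm"].copy()
    scanpy.pp.highly_variable_genes(
        a, flavor="seurat", min_mean=0.0125, max_mean=3, min_disp=0.5
    )
    ref = a.var_names[a.var["highly_variable"]]
    ref_top = set(
        a.var.loc[ref, "dispersions_norm"].sort_values(ascending=False)
        .head(60).index
    )
    overlap = len(set(hv) & ref_top)
    assert overlap >= 0.9 * min(len(hv), len(ref_top))  # up to bin-edge details


# ---------------------------------------------------------------------------
# rank-sum markers
# ---------------------------------------------------------------------------

def test_wilcoxon_identical_distributions_is_null():
    # the two groups hold exactly the same cells duplicated
    rng = np.random.default_rng(0)
    block = rng.poisson(2.0, size=(20, 5)) + 1
    counts = np.vstack([block, block])
    a = normalize(_adata_from_counts(counts))
    labels = np.array(["g1"] * 20 + ["g2"] * 20)
    res = wilcoxon_markers(a, labels, group="g1", min_pct=0.0)
    assert (res["p_value"] > 0.9).all()
    assert np.allclose(res["log_fc"], 0.0, atol=1e-12)


def test_wilcoxon_complete_separation_matches_exact_enumeration():
    # constant filler gene keeps library sizes informative for gene 0
    counts = np.array([[1, 50], [2, 50], [3, 50], [10, 50], [11, 50], [12, 50]])
    a = normalize(_adata_from_counts(counts))
    labels = np.array(["lo"] * 3 + ["hi"] * 3)
    res = wilcoxon_markers(a, labels, group="hi", min_pct=0.0).set_index("gene")
    x = a.layers["lognorm"].toarray()[3:, 0]
    y = a.layers["lognorm"].toarray()[:3, 0]
    assert res.loc["g0", "p_value"] == pytest.approx(0.1)
    assert res.loc["g0", "p_value"] == pytest.approx(oracle_ranksum_exact_p(x, y))


@pytest.mark.parametrize("seed", range(6))
def test_wilcoxon_matches_enumeration_oracle_small_groups(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(3, 7), rng.integers(3, 7)
    # tie-free values
    vals = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float))
    counts = np.column_stack([vals * 10, np.full(n1 + n2, 40.0)]).astype(int)
    a = normalize(_adata_from_counts(counts))
    labels = np.array(["g1"] * n1 + ["g2"] * n2)
    res = wilcoxon_markers(a, labels, group="g1", min_pct=0.0).set_index("gene")
    x = a.layers["lognorm"].toarray()[:n1, 0]
    y = a.layers["lognorm"].toarray()[n1:, 0]
    assert res.loc["g0", "p_value"] == pytest.approx(
        oracle_ranksum_exact_p(x, y), abs=1e-9
    )


def test_wilcoxon_planted_marker_detected(fibro_adata):
    labels = fibro_adata.obs["fibro_cluster"].astype(str).to_numpy()
    res = wilcoxon_markers(fibro_adata, labels, group="D").set_index("gene")
    for g in [f"D{i:02d}" for i in range(1, 9)]:
        assert res.loc[g, "q_value"] < 0.05
        assert res.loc[g, "log_fc"] > 0.25


# ---------------------------------------------------------------------------
# specificity filter and PRRX1 refinement
# ---------------------------------------------------------------------------

def _risk_table(rows):
    return pd.DataFrame(rows, columns=["gene", "risk_class"]).assign(
        cutpoint=1.0, max_statistic=2.0, p_value=0.01, q_value=0.05, hr=1.0
    )


def _marker_table(rows):
    return pd.DataFrame(rows, columns=["gene", "q_value", "log_fc"]).assign(
        group="fibroblast", pct_in=0.5, pct_out=0.1, p_value=0.001
    )


def test_specificity_filter_keeps_only_fibro_markers():
    risk = _risk_table([("fsp_lr", "ALL_LR"), ("epi_lr", "ALL_LR"),
                        ("fsp_hr", "ALL_HR"), ("none", "NONE")])
    markers = _marker_table([("fsp_lr", 0.001, 0.9), ("fsp_hr", 0.001, 0.5),
                             ("epi_lr", 0.9, -0.2)])
    hr, lr = specificity_filter(risk, markers)
    assert lr.genes == ("fsp_lr",)
    assert hr.genes == ("fsp_hr",)


def test_specificity_filter_strict_mode_excludes_shared_markers():
    risk = _risk_table([("shared", "ALL_LR")])
    markers = _marker_table([("shared", 0.001, 0.9)])
    epi = _marker_table([("shared", 0.001, 0.8)])
    _, lr = specificity_filter(risk, markers)
    assert lr.genes == ("shared",)
    _, lr_strict = specificity_filter(risk, markers,
                                      other_markers={"epithelial": epi})
    assert lr_strict.genes == ()


def test_prrx1_refine_recovers_low_enriched_genes():
    # PRRX1 marks the tumor-promoting B state (sharp, low baseline), so the
    # PRRX1-low stratum is D/A-enriched and planted D genes pass the filter;
    # a uniformly expressed gene does not
    cfg = small_scrna_cfg(
        seed=21, n_cells=2400,
        marker_modules={
            "A": [f"A{i:02d}" for i in range(1, 7)],
            "B": [f"B{i:02d}" for i in range(2, 7)],
            "B#prrx1": ["PRRX1"],
            "C": [f"C{i:02d}" for i in range(1, 7)],
            "D": [f"D{i:02d}" for i in range(1, 9)],
        },
        marker_log_fc={
            "A": float(np.log(4)), "B": float(np.log(4)),
            "B#prrx1": float(np.log(12)),
            "C": float(np.log(4)), "D": float(np.log(6)),
        },
        gene_mean_overrides={"PRRX1": 0.2},
    )
    fib = normalize(qc_filter(simulate_scrna(cfg)))
    fib = fib[(fib.obs["cell_type"] == "fibroblast").to_numpy()].copy()
    stromal_lr = GeneSet.from_iterable(
        "Stromal-LR", [f"D{i:02d}" for i in range(1, 9)] + ["G0001"]
    )
    refined = prrx1_refine(fib, stromal_lr)
    recovered = set(refined.genes) & {f"D{i:02d}" for i in range(1, 9)}
    assert len(recovered) >= 5
    assert "G0001" not in refined.genes  # uniform gene dropped


def test_prrx1_refine_empty_input_and_missing_gene():
    empty = prrx1_refine(None, GeneSet("Stromal-LR", ()))
    assert empty.genes == ()
    a = normalize(_adata_from_counts(np.ones((10, 3), dtype=int)))
    with pytest.raises(ValueError):
        prrx1_refine(a, GeneSet("s", ("g0",)), strat_gene="ABSENT")


def test_prrx1_refine_errors_when_stratum_empty():
    counts = np.ones((10, 3), dtype=int)
    a = normalize(_adata_from_counts(counts, genes=["PRRX1", "g1", "g2"]))
    with pytest.raises(ValueError, match="low"):
        prrx1_refine(a, GeneSet("s", ("g1",)))
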