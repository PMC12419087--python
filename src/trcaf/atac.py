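"""Superenhancer-driven gene calling from single-cell accessibility.

Two-step pipeline: (1) select accessibility peaks that are both unique to the
target fibroblast group (detection-fraction fold change plus a two-proportion
test) and significantly correlated with gene expression across metacells
within a genomic window of the TSS; (2) rank genes by their number of
qualifying peaks and split the scaled rank curve at the slope-1 inflection,
ROSE-style: genes above the inflection are superenhancer (SE) driven, the
rest typical-enhancer (TE) driven.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import module_score
from .scrna import GeneSet, _lognorm

__all__ = [
    "SECallResult",
    "group_specific_peaks",
    "peak_gene_links",
    "count_qualifying_peaks",
    "call_se_genes",
    "compare_se_te_scores",
]


def group_specific_peaks(
    atac: ad.AnnData,
    cluster_col: str = "cluster",
    target: str = "D",
    min_frac: float = 0.1,
    fold: float = 2.0,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Flag peaks uniquely accessible in the target cluster.

    A peak is specific iff its detection fraction in the target cluster is at
    least ``min_frac``, at least ``fold`` times the maximum fraction over the
    other clusters, and a two-proportion z test (target vs rest, BH-adjusted
    across peaks) gives q < ``q_cut``.  Returns the peak table (0-based
    half-open coordinates, sorted) with per-cluster fractions, the
    specificity q-value and the flag.
    """
    if atac.n_obs == 0 or atac.n_vars == 0:
        raise ValueError("empty accessibility matrix")
    clusters = atac.obs[cluster_col].astype(str).to_numpy()
    if not (clusters == target).any():
        raise ValueError(f"target cluster {target!r} is empty")
    X = atac.X
    det = (X > 0).astype(np.float64)
    uniq = sorted(set(clusters))
    frac = {}
    for c in uniq:
        mask = clusters == c
        frac[c] = np.asarray(det[mask].mean(axis=0)).ravel()
    tgt_mask = clusters == target
    n_t, n_r = int(tgt_mask.sum()), int((~tgt_mask).sum())
    x_t = np.asarray(det[tgt_mask].sum(axis=0)).ravel()
    x_r = np.asarray(det[~tgt_mask].sum(axis=0)).ravel()
    p_t, p_r = x_t / n_t, x_r / max(n_r, 1)
    pooled = (x_t + x_r) / (n_t + n_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled * (1 - pooled) * (1 / n_t + 1 / max(n_r, 1)))
        z = np.where(se > 0, (p_t - p_r) / se, 0.0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    qvals = multipletests(pvals, method="fdr_bh")[1]
    others = np.vstack([frac[c] for c in uniq if c != target]) \
        if len(uniq) > 1 else np.zeros((1, atac.n_vars))
    max_other = others.max(axis=0)
    specific = (
        (frac[target] >= min_frac)
        & (frac[target] >= fold * max_other)
        & (qvals < q_cut)
        & (p_t > p_r)
    )
    out = pd.DataFrame(
        {
            "peak_id": atac.var_names,
            "chrom": atac.var["chrom"].to_numpy(),
            "start": atac.var["start"].to_numpy(),
            "end": atac.var["end"].to_numpy(),
        }
    )
    for c in uniq:
        out[f"frac_{c}"] = frac[c]
    out["specificity_q"] = qvals
    out["specific"] = specific
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _metacell_assignment(clusters: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded random partition of cells into within-cluster metacells of size
    ~k (remainder cells join the last metacell of their cluster)."""
    assign = np.empty(clusters.size, dtype=int)
    next_id = 0
    for c in sorted(set(clusters.tolist())):
        idx = np.flatnonzero(clusters == c)
        idx = rng.permutation(idx)
        n_mc = max(1, idx.size // k)
        for j in range(n_mc):
            lo = j * k
            hi = idx.size if j == n_mc - 1 else (j + 1) * k
            assign[idx[lo:hi]] = next_id
            next_id += 1
    return assign


def peak_gene_links(
    atac: ad.AnnData,
    expr: ad.AnnData,
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 250_000,
    metacell_k: int = 20,
    r_cut: float = 0.45,
    q_cut: float = 0.05,
    seed: int = 0,
    cluster_col: str = "cluster",
    positive_only: bool = True,
) -> pd.DataFrame:
    """Correlate peak accessibility with gene expression across metacells.

    Cells (shared between modalities, matched by id) are partitioned within
    each cluster into seeded random metacells of size ``metacell_k``; for
    every (peak, gene) pair with peak midpoint within ``window`` of the TSS,
    the Pearson correlation of metacell-mean log-normalized accessibility and
    expression is tested, with BH adjustment across all tested pairs.  A pair
    is a retained link iff r >= ``r_cut`` (signed, enhancer logic; absolute
    with ``positive_only=False``) and q < ``q_cut``.

    Returns all tested pairs with columns peak_id, gene, r, p, q, distance
    and the ``retained`` flag.
    """
    if list(atac.obs_names) != list(expr.obs_names):
        shared = [c for c in atac.obs_names if c in set(expr.obs_names)]
        if not shared:
            raise ValueError("no shared cells between modalities")
        atac = atac[shared]
        expr = expr[shared]
    clusters = atac.obs[cluster_col].astype(str).to_numpy()
    rng = np.random.default_rng(seed)
    assign = _metacell_assignment(clusters, metacell_k, rng)
    n_mc = assign.max() + 1
    if n_mc < 3:
        raise ValueError("fewer than 3 metacells; lower metacell_k")

    A = _normalized_dense(atac)
    E = _normalized_dense(expr)
    M_a = np.zeros((n_mc, A.shape[1]))
    M_e = np.zeros((n_mc, E.shape[1]))
    for mc in range(n_mc):
        mask = assign == mc
        M_a[mc] = A[mask].mean(axis=0)
        M_e[mc] = E[mask].mean(axis=0)

    za = _zscore_cols(M_a)
    ze = _zscore_cols(M_e)
    peak_pos = peaks.set_index("peak_id")
    mid = ((peak_pos["start"] + peak_pos["end"]) // 2).astype(int)
    peak_idx = {p: i for i, p in enumerate(atac.var_names)}
    gene_idx = {g: i for i, g in enumerate(expr.var_names)}

    rows = []
    for _, g in tss.iterrows():
        if g["gene_id"] not in gene_idx:
            continue
        same_chrom = peak_pos["chrom"] == g["chrom"]
        dist = (mid[same_chrom] - int(g["tss_pos"])).abs()
        for pid, dval in dist[dist <= window].items():
            if pid not in peak_idx:
                continue
            r = float(np.mean(za[:, peak_idx[pid]] * ze[:, gene_idx[g["gene_id"]]]))
            rows.append((pid, g["gene_id"], r, int(dval)))
    if not rows:
        raise ValueError("no candidate peak-gene pairs within the window")
    out = pd.DataFrame(rows, columns=["peak_id", "gene", "r", "distance"])
    r = out["r"].to_numpy().clip(-1.0, 1.0)
    df = n_mc - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / np.maximum(1e-12, 1.0 - r**2))
    out["p"] = 2 * stats.t.sf(np.abs(tstat), df=df)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    strength = out["r"] if positive_only else out["r"].abs()
    out["retained"] = (strength >= r_cut) & (out["q"] < q_cut)
    return out[["peak_id", "gene", "r", "p", "q", "distance", "retained"]]


def _normalized_dense(m: ad.AnnData) -> np.ndarray:
    """Log1p library-size normalization that keeps zero-count cells (as zero
    rows) so the two modalities stay cell-aligned."""
    from .scrna import LOGNORM

    if LOGNORM in m.layers:
        return _lognorm(m)
    X = np.asarray(m.X.todense() if hasattr(m.X, "todense") else m.X, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(1e4 * X / totals)


def _zscore_cols(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0, keepdims=True)
    sd = M.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (M - mu) / sd


def count_qualifying_peaks(links: pd.DataFrame, peaks: pd.DataFrame) -> pd.Series:
    """Number of distinct specific peaks linked to each gene.

    ``links`` is the peak_gene_links output (only retained rows count);
    ``peaks`` the group_specific_peaks table (only specific peaks count).
    Genes with no qualifying peak are omitted (they never enter the ranking).
    """
    specific = set(peaks.loc[peaks["specific"], "peak_id"])
    kept = links[links["retained"] & links["peak_id"].isin(specific)]
    counts = (
        kept.drop_duplicates(["peak_id", "gene"])
        .groupby("gene")
        .size()
        .sort_index()
    )
    counts.name = "n_qualifying_peaks"
    return counts


@dataclass(frozen=True)
class SECallResult:
    """Scaled rank curve of qualifying-peak counts with the SE/TE partition."""

    table: pd.DataFrame           # gene, count, x, y, label (rank-ascending)
    inflection: tuple[float, float] | None

    @property
    def se_genes(self) -> GeneSet:
        return GeneSet.from_iterable(
            "SE", self.table.loc[self.table["label"] == "SE", "gene"]
        )

    @property
    def te_genes(self) -> GeneSet:
        return GeneSet.from_iterable(
            "TE", self.table.loc[self.table["label"] == "TE", "gene"]
        )


def call_se_genes(counts: pd.Series, slope_window: int = 5) -> SECallResult:
    """Split genes into SE- vs TE-driven at the slope-1 inflection.

    Genes are sorted ascending by (count, gene id) and both axes scaled to
    [0, 1]; the numerical slope uses centered differences over a
    ``slope_window``-point window (clamped at the edges).  Scanning left to
    right, the rightmost upward crossing of slope 1 defines the inflection
    (placed on the last slope<=1 point before the crossing); SE genes are
    those with scaled count strictly above the inflection, so ties at the
    cutoff fall to TE.  Zero dynamic range (all counts equal) yields all-TE
    with a warning.
    """
    counts = pd.Series(counts).astype(float)
    if len(counts) < 3:
        raise ValueError("need at least 3 genes with qualifying peaks")
    order = sorted(counts.index, key=lambda g: (counts[g], str(g)))
    c = counts.loc[order].to_numpy()
    n = len(c)
    c_min, c_max = c.min(), c.max()
    x = np.arange(1, n + 1) / n
    if c_max == c_min:
        warnings.warn("zero dynamic range in peak counts; all genes called TE")
        table = pd.DataFrame(
            {"gene": order, "count": c.astype(int), "x": x,
             "y": np.zeros(n), "label": "TE"}
        )
        return SECallResult(table=table, inflection=None)
    y = (c - c_min) / (c_max - c_min)
    half = slope_window // 2
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    slope = (y[hi] - y[lo]) / (x[hi] - x[lo])
    above = slope > 1.0
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if crossings.size == 0:
        labels = np.full(n, "TE", dtype=object)
        inflection = None
    else:
        i_star = int(crossings[-1]) - 1     # last point on the slope<=1 side
        inflection = (float(x[i_star]), float(y[i_star]))
        labels = np.where(y > y[i_star], "SE", "TE").astype(object)
    table = pd.DataFrame(
        {"gene": order, "count": c.astype(int), "x": x, "y": y, "label": labels}
    )
    return SECallResult(table=table, inflection=inflection)


def compare_se_te_scores(
    m: ad.AnnData,
    se: GeneSet,
    te: GeneSet,
    cluster_col: str = "fibro_cluster",
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster paired comparison of SE vs TE module scores.

    Both sets are scored with the same binning seed (identical sets therefore
    give a delta of exactly zero); within each cluster the per-cell score
    difference is tested with a two-sided one-sample t test against zero.
    """
    if len(se) == 0 or len(te) == 0:
        raise ValueError("SE and TE gene sets must be non-empty")
    s_se = module_score(m, se, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    s_te = module_score(m, te, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    diff = s_se.score - s_te.score
    clusters = m.obs[cluster_col]
    rows = []
    for c in clusters.cat.categories if hasattr(clusters, "cat") \
            else sorted(clusters.dropna().unique()):
        mask = (clusters == c).to_numpy()
        if not mask.any():
            continue
        d = diff[mask]
        if np.allclose(d, d[0]):
            p = 1.0 if np.allclose(d, 0) else 0.0
        else:
            p = float(stats.ttest_1samp(d, 0.0).pvalue)
        rows.append(
            dict(cluster=c,
                 mean_se_score=float(s_se.score[mask].mean()),
                 mean_te_score=float(s_te.score[mask].mean()),
                 delta=float(d.mean()),
                 p_value=p)
        )
    return pd.DataFrame(rows)
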