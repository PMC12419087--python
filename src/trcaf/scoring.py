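"""Binned-control gene-set module scores and cluster-proportion shift tests.

The module score of a gene set in a cell is the mean log-normalized
expression of the set genes minus the mean over expression-matched control
genes: genes are ranked by dataset-average expression into equal-frequency
bins, and each set gene contributes ``n_ctrl`` controls sampled from its own
bin (excluding set genes).  The subtraction removes the cell's global
expression level, so the score isolates set-specific enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .scrna import GeneSet, _lognorm

__all__ = [
    "ModuleScoreResult",
    "module_score",
    "classify_high",
    "proportion_shift",
]


@dataclass(frozen=True)
class ModuleScoreResult:
    cell_ids: tuple[str, ...]
    score: np.ndarray
    n_bins: int
    n_ctrl: int
    seed: int
    geneset_name: str

    def to_series(self) -> pd.Series:
        return pd.Series(self.score, index=list(self.cell_ids),
                         name=f"score_{self.geneset_name}")


def module_score(
    m: ad.AnnData,
    geneset: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Per-cell module score with binned control genes.

    Genes are ordered by (dataset-average expression, gene id) and cut into
    ``n_bins`` equal-frequency bins; for each set gene, ``n_ctrl`` control
    genes are drawn from its bin excluding set genes (with replacement if the
    bin is smaller, and falling back to the whole bin when it contains only
    set genes, so a set covering all genes scores ~0).  Deterministic given
    the seed.
    """
    X = _lognorm(m)
    genes = np.asarray(m.var_names)
    set_idx = np.asarray([m.var_names.get_loc(g) for g in geneset.genes
                          if g in m.var_names], dtype=int)
    if set_idx.size == 0:
        raise ValueError(f"no gene of set {geneset.name!r} present in matrix")
    avg = X.mean(axis=0)
    order = np.lexsort((genes, avg))  # deterministic: avg, then gene id
    ranks = np.empty(len(genes), dtype=int)
    ranks[order] = np.arange(len(genes))
    bins = (ranks * n_bins) // len(genes)
    in_set = np.zeros(len(genes), dtype=bool)
    in_set[set_idx] = True

    rng = np.random.default_rng(seed)
    ctrl_parts = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if pool.size == 0:
            pool = np.flatnonzero(bins == bins[gi])
        # canonical pool order (gene id) so scores are invariant to the
        # storage order of genes in the matrix
        pool = pool[np.argsort(genes[pool], kind="stable")]
        replace = pool.size < n_ctrl
        ctrl_parts.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl_parts)
    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return ModuleScoreResult(
        cell_ids=tuple(m.obs_names),
        score=score,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        geneset_name=geneset.name,
    )


def classify_high(
    scores: ModuleScoreResult,
    method: str = "positive",
    q: float = 0.25,
) -> pd.Series:
    """Flag score-high cells: ``positive`` flags score > 0; ``quantile`` flags
    the top ceil(q*n) cells, ties broken by cell id."""
    s = scores.to_series()
    if method == "positive":
        flag = s > 0
    elif method == "quantile":
        if not 0 < q < 1:
            raise ValueError("q must be in (0, 1)")
        n_high = int(np.ceil(q * len(s)))
        order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], s.index[i]))
        flag = pd.Series(False, index=s.index)
        flag.iloc[order[:n_high]] = True
    else:
        raise ValueError(f"unknown method: {method!r}")
    flag.name = "high"
    return flag


def proportion_shift(
    m: ad.AnnData,
    cluster_col: str = "fibro_cluster",
    condition_col: str = "condition",
    sample_col: str = "sample",
    test: str = "t",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample fibroblast cluster fractions and tumor-vs-normal tests.

    Fractions are computed among fibroblasts only (cells with a non-null
    cluster label; the denominator is the sample's fibroblast count).  Each
    cluster is tested across samples with a two-sided Welch t test (default)
    or rank-sum.  Returns ``(proportion_table, shift_table)``.
    """
    obs = m.obs
    fib = obs[obs[cluster_col].notna()]
    if fib.empty:
        raise ValueError("no cells carry a cluster label")
    clusters = [c for c in fib[cluster_col].cat.categories] \
        if hasattr(fib[cluster_col], "cat") else sorted(fib[cluster_col].unique())
    counts = (
        fib.groupby([sample_col, cluster_col], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=clusters, fill_value=0)
    )
    counts = counts[counts.sum(axis=1) > 0]
    fracs = counts.div(counts.sum(axis=1), axis=0)
    cond_of = (
        fib.drop_duplicates(sample_col)
        .set_index(sample_col)[condition_col]
        .astype(str)
        .reindex(counts.index)
    )
    for cond in ("normal", "tumor"):
        if (cond_of == cond).sum() < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 samples")

    rows = []
    for s in counts.index:
        for c in clusters:
            rows.append(
                dict(sample=s, condition=cond_of[s], cluster=c,
                     n_cells=int(counts.loc[s, c]),
                     fraction=float(fracs.loc[s, c]))
            )
    prop_table = pd.DataFrame(rows)

    shift_rows = []
    for c in clusters:
        a = fracs.loc[cond_of == "normal", c].to_numpy()
        b = fracs.loc[cond_of == "tumor", c].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        elif test == "t":
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        elif test == "wilcoxon":
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            raise ValueError(f"unknown test: {test!r}")
        shift_rows.append(
            dict(cluster=c, mean_normal=float(a.mean()),
                 mean_tumor=float(b.mean()), p_value=p)
        )
    return prop_table, pd.DataFrame(shift_rows)
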