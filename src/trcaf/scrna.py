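"""Single-cell QC, normalization, variable genes, markers and gene-set refinement.

Cell matrices are AnnData objects: raw counts in ``.X`` (sparse), per-cell
metadata in ``.obs`` and log-normalized expression in ``.layers['lognorm']``
once :func:`normalize` has run.  Fold changes are natural-log throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "qc_filter",
    "normalize",
    "find_variable_genes",
    "wilcoxon_markers",
    "specificity_filter",
    "prrx1_refine",
]

LOGNORM = "lognorm"


@dataclass(frozen=True)
class GeneSet:
    """Named, ordered gene list with unique ids."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_iterable(cls, name: str, genes) -> "GeneSet":
        deduped = list(dict.fromkeys(genes))
        return cls(name, tuple(deduped))


def _counts(m: ad.AnnData) -> sp.csr_matrix:
    return sp.csr_matrix(m.X)


def _lognorm(m: ad.AnnData) -> np.ndarray:
    if LOGNORM not in m.layers:
        raise ValueError("normalized layer missing; run normalize() first")
    layer = m.layers[LOGNORM]
    return layer.toarray() if sp.issparse(layer) else np.asarray(layer)


def ensure_qc(m: ad.AnnData) -> None:
    """(Re)compute per-cell QC stats from the raw counts."""
    from .simulate import _attach_qc

    _attach_qc(m)


def qc_filter(
    m: ad.AnnData,
    min_genes: int = 200,
    max_genes: int = 6000,
    min_umi: int = 1000,
    max_mito: float = 0.25,
) -> ad.AnnData:
    """Retain cells with more than ``min_genes`` and fewer than ``max_genes``
    detected genes, more than ``min_umi`` total counts and a mitochondrial
    fraction of at most ``max_mito``.  The gene roster is unchanged."""
    if "n_genes_detected" not in m.obs:
        ensure_qc(m)
    keep = (
        (m.obs["n_genes_detected"] > min_genes)
        & (m.obs["n_genes_detected"] < max_genes)
        & (m.obs["total_umi"] > min_umi)
        & (m.obs["mito_fraction"] <= max_mito)
    ).to_numpy()
    return m[keep].copy()


def normalize(m: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Per-cell log normalization: log(1 + scale_factor * count / total).

    Cells with zero total counts cannot be normalized and are dropped with a
    warning.  Raw counts are left untouched; the result is stored in
    ``.layers['lognorm']``.
    """
    X = _counts(m)
    totals = np.asarray(X.sum(axis=1)).ravel()
    ok = totals > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} zero-count cells")
    out = m[ok].copy()
    X = sp.csr_matrix(out.X, dtype=float)
    inv = scale_factor / totals[ok]
    X = sp.diags(inv) @ X
    X.data = np.log1p(X.data)
    out.layers[LOGNORM] = X.tocsr()
    return out


def find_variable_genes(
    m: ad.AnnData,
    n_top: int = 1000,
    disp_cut: float = 0.5,
    mean_lo: float = 0.0125,
    mean_hi: float = 3.0,
    n_mean_bins: int = 20,
) -> list[str]:
    """Mean/dispersion variable-gene selection (classic Seurat flavor).

    On the back-scaled data (expm1 of log-normalized values): per-gene mean
    and dispersion = variance/mean; dispersions are z-standardized within
    equal-width bins of log1p(mean); genes inside the mean window with
    standardized dispersion above ``disp_cut`` are kept, and the top ``n_top``
    by standardized dispersion are returned (all survivors, with a warning,
    if fewer pass).
    """
    X = np.expm1(_lognorm(m))
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
        log_disp = np.log(disp)
    log_mean = np.log1p(mean)
    df = pd.DataFrame(
        {"gene": m.var_names, "mean": log_mean, "disp": log_disp}
    )
    df["bin"] = pd.cut(df["mean"], bins=n_mean_bins)
    grp = df.groupby("bin", observed=True)["disp"]
    centered = df["disp"] - grp.transform("mean")
    scale = grp.transform("std")
    df["disp_norm"] = (centered / scale).replace([np.inf, -np.inf], np.nan).fillna(0.0)
    survivors = df[
        (df["mean"] > mean_lo)
        & (df["mean"] < mean_hi)
        & (df["disp_norm"] > disp_cut)
    ]
    if len(survivors) < n_top:
        warnings.warn(
            f"only {len(survivors)} genes pass the variable-gene window "
            f"(requested {n_top})"
        )
    top = survivors.sort_values(["disp_norm", "gene"], ascending=[False, True])
    return top["gene"].head(n_top).tolist()


def _group_labels(m: ad.AnnData, labels) -> np.ndarray:
    if isinstance(labels, str):
        return m.obs[labels].astype(object).to_numpy()
    arr = np.asarray(labels, dtype=object)
    if arr.shape != (m.n_obs,):
        raise ValueError("labels length must match number of cells")
    return arr


def wilcoxon_markers(
    m: ad.AnnData,
    labels,
    group: str,
    min_pct: float = 0.1,
    lfc_eps: float = 1.0,
) -> pd.DataFrame:
    """Rank-sum marker test of ``group`` cells against the rest.

    Two-sided Wilcoxon rank-sum on log-normalized values (exact for small
    tie-free groups, tie-corrected normal approximation otherwise), BH
    q-values over the tested genes.  log_fc is the natural-log fold change of
    back-scaled group means: ln(mean expm1 in + 1) - ln(mean expm1 out + 1).
    Only genes detected in at least ``min_pct`` of either group are tested.
    """
    lab = _group_labels(m, labels)
    mask = lab == group
    if not mask.any():
        raise ValueError(f"group {group!r} is empty")
    if mask.all():
        raise ValueError("comparison group is empty")
    if mask.sum() == 1:
        warnings.warn("single-cell group: marker test has minimal power")
    X = _lognorm(m)
    xin, xout = X[mask], X[~mask]
    pct_in = (xin > 0).mean(axis=0)
    pct_out = (xout > 0).mean(axis=0)
    tested = (pct_in >= min_pct) | (pct_out >= min_pct)
    if not tested.any():
        return pd.DataFrame(
            columns=["gene", "group", "log_fc", "pct_in", "pct_out",
                     "p_value", "q_value"]
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            xin[:, tested], xout[:, tested],
            alternative="two-sided", method="auto", axis=0,
        )
    pvals = np.atleast_1d(res.pvalue)
    mean_in = np.expm1(xin[:, tested]).mean(axis=0)
    mean_out = np.expm1(xout[:, tested]).mean(axis=0)
    log_fc = np.log(mean_in + lfc_eps) - np.log(mean_out + lfc_eps)
    out = pd.DataFrame(
        {
            "gene": np.asarray(m.var_names)[tested],
            "group": group,
            "log_fc": log_fc,
            "pct_in": pct_in[tested],
            "pct_out": pct_out[tested],
            "p_value": pvals,
        }
    )
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values(["p_value", "gene"]).reset_index(drop=True)


def _significant_positive(markers: pd.DataFrame, q_cut: float, lfc_cut: float) -> set[str]:
    hit = markers[(markers["q_value"] < q_cut) & (markers["log_fc"] > lfc_cut)]
    return set(hit["gene"])


def specificity_filter(
    risk: pd.DataFrame,
    markers: pd.DataFrame,
    target_type: str = "fibroblast",
    q_cut: float = 0.05,
    lfc_cut: float = 0.25,
    other_markers: Mapping[str, pd.DataFrame] | None = None,
) -> tuple[GeneSet, GeneSet]:
    """Restrict risk genes to those specifically expressed in the target type.

    A risk gene is stromal iff it is a significant positive marker of
    ``target_type`` (q < q_cut, log_fc > lfc_cut).  With ``other_markers``
    (marker tables for other cell types), a stricter mode additionally
    requires the gene not to be a significant positive marker of any of them.
    Returns (Stromal-HR, Stromal-LR), preserving risk class.
    """
    if risk.empty:
        raise ValueError("empty risk table")
    specific = _significant_positive(markers, q_cut, lfc_cut)
    if other_markers:
        for other in other_markers.values():
            specific -= _significant_positive(other, q_cut, lfc_cut)
    hr = [g for g in risk.loc[risk["risk_class"] == "ALL_HR", "gene"] if g in specific]
    lr = [g for g in risk.loc[risk["risk_class"] == "ALL_LR", "gene"] if g in specific]
    return (
        GeneSet.from_iterable("Stromal-HR", hr),
        GeneSet.from_iterable("Stromal-LR", lr),
    )


def prrx1_refine(
    m: ad.AnnData,
    stromal_lr: GeneSet,
    strat_gene: str = "PRRX1",
    q_cut: float = 0.05,
    lfc_cut: float = 0.25,
    split: str = "nonzero",
    min_pct: float = 0.1,
) -> GeneSet:
    """Refine Stromal-LR to genes enriched in the ``strat_gene``-low stratum.

    Fibroblasts are split into strat-gene-high vs -low (default: nonzero vs
    zero normalized expression, dropout-tolerant; ``split='median'`` uses the
    median).  Stromal-LR members that are significant positive markers of the
    low stratum (q < q_cut, log_fc > lfc_cut) form the refined set.
    """
    if len(stromal_lr) == 0:
        return GeneSet("rStromal-LR", ())
    if strat_gene not in m.var_names:
        raise ValueError(f"stratification gene {strat_gene!r} not in matrix")
    X = _lognorm(m)
    vals = X[:, m.var_names.get_loc(strat_gene)]
    if split == "nonzero":
        high = vals > 0
    elif split == "median":
        high = vals > np.median(vals)
    else:
        raise ValueError(f"unknown split: {split!r}")
    for name, mask in ((f"{strat_gene}-high", high), (f"{strat_gene}-low", ~high)):
        if not mask.any():
            raise ValueError(f"stratum {name} is empty")
    labels = np.where(high, "high", "low")
    markers = wilcoxon_markers(m, labels, group="low", min_pct=min_pct)
    keep = _significant_positive(markers, q_cut, lfc_cut)
    return GeneSet.from_iterable(
        "rStromal-LR", [g for g in stromal_lr.genes if g in keep]
    )
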