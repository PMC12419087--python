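"""Seeded synthetic data with the statistical structure the pipeline assumes.

Three generators:

* ``simulate_scrna`` -- negative-binomial scRNA counts (gamma-Poisson mixture,
  lognormal library sizes) over a mixed cell-type population whose fibroblasts
  carry four subclusters (A-D) with planted marker modules and
  condition-dependent cluster proportions.
* ``simulate_survival_cohort`` -- a proportional-hazards cohort whose
  exponential event hazard depends log-linearly on z-scored expression of
  planted effect genes, with administrative censoring at a fixed horizon.
* ``simulate_scatac`` -- Bernoulli peak-by-cell accessibility with planted
  Group-D-specific peaks placed inside the linkage window of their gene's TSS,
  returning the ground-truth peak-gene links for recovery tests.

Every generator is a pure function of its config (including the seed): one
``numpy.random.default_rng`` per call, no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .survival import SurvivalCohort

__all__ = [
    "ScrnaSimConfig",
    "SurvivalSimConfig",
    "AtacSimConfig",
    "simulate_scrna",
    "simulate_survival_cohort",
    "simulate_scatac",
    "pseudobulk_log_cpm",
]

CELL_TYPES = ("epithelial", "T", "B", "myeloid", "fibroblast")
FIBRO_CLUSTERS = ("A", "B", "C", "D")
CONDITIONS = ("normal", "tumor")


def _check_props(p: Mapping[str, float], keys: Sequence[str], what: str) -> np.ndarray:
    vec = np.array([float(p[k]) for k in keys])
    if abs(vec.sum() - 1.0) > 1e-9 or (vec < 0).any():
        raise ValueError(f"{what} proportions must be non-negative and sum to 1")
    return vec


def _module_target(key: str) -> str:
    """Module keys are '<cluster-or-celltype>' or '<target>#tag' so several
    disjoint modules may target the same population with different effects."""
    return key.split("#", 1)[0]


@dataclass
class ScrnaSimConfig:
    n_genes: int = 1000
    n_cells: int = 4000
    cell_type_props: Mapping[str, float] = field(
        default_factory=lambda: {
            "epithelial": 0.35, "T": 0.25, "B": 0.10,
            "myeloid": 0.10, "fibroblast": 0.20,
        }
    )
    fibro_cluster_props_by_condition: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "normal": {"A": 0.35, "B": 0.10, "C": 0.20, "D": 0.35},
            "tumor": {"A": 0.15, "B": 0.50, "C": 0.20, "D": 0.15},
        }
    )
    marker_modules: Mapping[str, Sequence[str]] = field(default_factory=dict)
    marker_log_fc: float | Mapping[str, float] = float(np.log(4.0))
    nb_dispersion: float = 0.5
    library_size_mean: int = 4000
    n_samples_per_condition: int = 8
    seed: int = 0
    n_mito_genes: int = 10
    mito_fraction_target: float = 0.08
    marker_base_mean: float | None = 0.5
    gene_mean_overrides: Mapping[str, float] = field(default_factory=dict)
    gene_ids: Sequence[str] | None = None
    library_size_sigma: float = 0.3

    def module_genes(self) -> list[str]:
        seen: list[str] = []
        for key in self.marker_modules:
            for g in self.marker_modules[key]:
                seen.append(g)
        return seen

    def log_fc_for(self, key: str) -> float:
        if isinstance(self.marker_log_fc, Mapping):
            return float(self.marker_log_fc[key])
        return float(self.marker_log_fc)

    def validate(self) -> None:
        _check_props(self.cell_type_props, CELL_TYPES, "cell type")
        for cond in CONDITIONS:
            _check_props(
                self.fibro_cluster_props_by_condition[cond],
                FIBRO_CLUSTERS, f"fibroblast cluster ({cond})",
            )
        mods = self.module_genes()
        if len(mods) != len(set(mods)):
            raise ValueError("marker modules must be disjoint")
        if self.n_genes < len(mods) + self.n_mito_genes:
            raise ValueError("n_genes smaller than planted marker + mito genes")
        if isinstance(self.marker_log_fc, Mapping):
            bad = [k for k, v in self.marker_log_fc.items() if v <= 0]
        else:
            bad = [] if self.marker_log_fc > 0 else ["*"]
        if bad:
            raise ValueError("marker_log_fc must be positive")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("nb_dispersion and library_size_mean must be positive")
        for key in self.marker_modules:
            tgt = _module_target(key)
            if tgt not in FIBRO_CLUSTERS and tgt not in CELL_TYPES:
                raise ValueError(f"unknown marker module target: {tgt!r}")


def _build_roster(cfg: ScrnaSimConfig) -> list[str]:
    if cfg.gene_ids is not None:
        roster = list(cfg.gene_ids)
        if len(roster) != cfg.n_genes:
            raise ValueError("gene_ids length must equal n_genes")
    else:
        roster = list(dict.fromkeys(cfg.module_genes()))
        roster += [f"MT-{i + 1}" for i in range(cfg.n_mito_genes)]
        i = 1
        while len(roster) < cfg.n_genes:
            gid = f"G{i:04d}"
            if gid not in roster:
                roster.append(gid)
            i += 1
    missing = [g for g in cfg.module_genes() if g not in roster]
    if missing:
        raise ValueError(f"marker genes outside gene roster: {missing[:5]}")
    return roster


def simulate_scrna(
    cfg: ScrnaSimConfig,
    fibro_clusters: Sequence[str] | None = None,
) -> ad.AnnData:
    """Generate an scRNA count matrix (cells x genes AnnData).

    Counts are gamma-Poisson (negative binomial with dispersion
    ``nb_dispersion``); marker-module genes have their mean multiplied by
    ``exp(marker_log_fc)`` in the module's target cluster or cell type.
    ``fibro_clusters`` (length n_cells) forces every cell to be a fibroblast
    with the given A-D label -- used to pair an expression matrix with a
    simulated accessibility matrix cell-for-cell.

    obs columns: cell_type, fibro_cluster (A-D, NA outside fibroblasts),
    sample, condition, n_genes_detected, total_umi, mito_fraction.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    roster = _build_roster(cfg)
    n_genes = len(roster)
    gene_index = {g: i for i, g in enumerate(roster)}

    n = cfg.n_cells
    n_normal = n // 2
    condition = np.array(["normal"] * n_normal + ["tumor"] * (n - n_normal))
    sample_idx = rng.integers(0, max(1, cfg.n_samples_per_condition), size=n)
    sample = np.array(
        [f"{c}_s{j + 1}" for c, j in zip(condition, sample_idx)], dtype=object
    )

    type_p = _check_props(cfg.cell_type_props, CELL_TYPES, "cell type")
    cell_type = rng.choice(CELL_TYPES, size=n, p=type_p) if n else np.array([], dtype=object)
    fibro_cluster = np.full(n, None, dtype=object)
    if fibro_clusters is not None:
        fc = np.asarray(fibro_clusters, dtype=object)
        if fc.shape != (n,):
            raise ValueError("fibro_clusters must have length n_cells")
        bad = set(fc) - set(FIBRO_CLUSTERS)
        if bad:
            raise ValueError(f"unknown fibroblast clusters: {sorted(bad)}")
        cell_type = np.full(n, "fibroblast", dtype=object)
        fibro_cluster = fc.copy()
    else:
        for cond in CONDITIONS:
            mask = (condition == cond) & (cell_type == "fibroblast")
            if mask.any():
                p = _check_props(
                    cfg.fibro_cluster_props_by_condition[cond], FIBRO_CLUSTERS, cond
                )
                fibro_cluster[mask] = rng.choice(FIBRO_CLUSTERS, size=mask.sum(), p=p)

    # gene base means (expected counts per cell at the mean library size)
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base = raw / raw.sum() * cfg.library_size_mean
    if cfg.marker_base_mean is not None:
        for g in cfg.module_genes():
            base[gene_index[g]] = cfg.marker_base_mean
    if cfg.n_mito_genes and cfg.gene_ids is None:
        per_mt = cfg.mito_fraction_target * cfg.library_size_mean / cfg.n_mito_genes
        for i in range(cfg.n_mito_genes):
            base[gene_index[f"MT-{i + 1}"]] = per_mt
    for g, v in cfg.gene_mean_overrides.items():
        base[gene_index[g]] = float(v)

    obs = pd.DataFrame(
        {
            "cell_type": pd.Categorical(cell_type, categories=list(CELL_TYPES)),
            "fibro_cluster": pd.Categorical(fibro_cluster, categories=list(FIBRO_CLUSTERS)),
            "sample": sample,
            "condition": pd.Categorical(condition, categories=list(CONDITIONS)),
        },
        index=[f"cell_{i:05d}" for i in range(n)],
    )
    var = pd.DataFrame(index=pd.Index(roster, name="gene"))

    if n == 0:
        X = sp.csr_matrix((0, n_genes), dtype=np.int64)
        adata = ad.AnnData(X=X, obs=obs, var=var)
        adata.obs["n_genes_detected"] = np.array([], dtype=int)
        adata.obs["total_umi"] = np.array([], dtype=int)
        adata.obs["mito_fraction"] = np.array([], dtype=float)
        return adata

    lib = rng.lognormal(
        mean=-0.5 * cfg.library_size_sigma ** 2, sigma=cfg.library_size_sigma, size=n
    )
    mean = lib[:, None] * base[None, :]
    for key in cfg.marker_modules:
        tgt = _module_target(key)
        if tgt in FIBRO_CLUSTERS:
            cells = np.asarray(fibro_cluster == tgt)
        else:
            cells = np.asarray(cell_type == tgt)
        gidx = [gene_index[g] for g in cfg.marker_modules[key]]
        if cells.any() and gidx:
            mean[np.ix_(cells, gidx)] *= np.exp(cfg.log_fc_for(key))

    shape = 1.0 / cfg.nb_dispersion
    lam = mean * rng.gamma(shape=shape, scale=cfg.nb_dispersion, size=mean.shape)
    counts = rng.poisson(lam)
    X = sp.csr_matrix(counts, dtype=np.int64)

    adata = ad.AnnData(X=X, obs=obs, var=var)
    _attach_qc(adata)
    return adata


def _attach_qc(adata: ad.AnnData) -> None:
    X = adata.X
    total = np.asarray(X.sum(axis=1)).ravel()
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith("MT-")
    mito = np.asarray(X[:, np.flatnonzero(mito_mask)].sum(axis=1)).ravel() \
        if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    adata.obs["n_genes_detected"] = detected.astype(int)
    adata.obs["total_umi"] = total.astype(int)
    adata.obs["mito_fraction"] = frac.astype(float)


def pseudobulk_log_cpm(adata: ad.AnnData, sample_col: str = "sample") -> pd.DataFrame:
    """Unweighted per-sample sum of counts, CPM-normalized then log1p.

    Returns a genes x samples DataFrame (bulk-cohort analogue of the
    single-cell population the signatures refer to).
    """
    samples = pd.Index(sorted(adata.obs[sample_col].astype(str).unique()))
    mat = np.zeros((adata.n_vars, len(samples)))
    X = sp.csr_matrix(adata.X)
    codes = adata.obs[sample_col].astype(str).to_numpy()
    for j, s in enumerate(samples):
        mask = codes == s
        mat[:, j] = np.asarray(X[mask].sum(axis=0)).ravel()
    totals = mat.sum(axis=0, keepdims=True)
    totals[totals == 0] = 1.0
    cpm = mat / totals * 1e6
    return pd.DataFrame(np.log1p(cpm), index=adata.var_names, columns=samples)


@dataclass
class SurvivalSimConfig:
    n_samples: int = 300
    baseline_hazard: float = 0.1
    effect_genes: Mapping[str, float] = field(default_factory=dict)
    censor_horizon: float = 10.0
    seed: int = 0
    n_genes: int | None = None
    gene_ids: Sequence[str] | None = None
    early_censor_frac: float = 0.0
    # co-regulated programs: genes of a group share a latent N(0,1) factor
    # with this loading in their log expression (lognormal path only)
    factor_groups: Mapping[str, Sequence[str]] = field(default_factory=dict)
    factor_loading: float = 0.9

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if not self.censor_horizon > 0:
            raise ValueError("censor_horizon must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        for g, c in self.effect_genes.items():
            if not np.isfinite(c):
                raise ValueError(f"non-finite coefficient for {g}")
        if not 0.0 <= self.early_censor_frac <= 1.0:
            raise ValueError("early_censor_frac must be in [0, 1]")


def simulate_survival_cohort(
    cfg: SurvivalSimConfig,
    expr_source: ad.AnnData | None = None,
) -> SurvivalCohort:
    """Proportional-hazards cohort with planted log-linear gene effects.

    Expression is either the per-sample pseudo-bulk of ``expr_source`` (sum of
    counts per sample, CPM, log1p) or lognormal draws over the configured gene
    roster.  The event hazard for sample i is
    ``baseline_hazard * exp(sum_g coef_g * z_gi)`` with z the per-gene z-score
    of log1p expression; event times are exponential and censored at
    ``censor_horizon`` (plus optional uniform early censoring).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if expr_source is not None:
        expr = pseudobulk_log_cpm(expr_source)
        if expr.shape[1] < 2:
            raise ValueError("expression source yields fewer than 2 samples")
    else:
        roster = list(cfg.gene_ids) if cfg.gene_ids is not None else None
        if roster is None:
            roster = list(cfg.effect_genes)
            n_extra = 0 if cfg.n_genes is None else cfg.n_genes - len(roster)
            roster += [f"NULL{i + 1:04d}" for i in range(max(0, n_extra))]
        missing = [g for g in cfg.effect_genes if g not in roster]
        if missing:
            raise ValueError(f"effect genes outside roster: {missing[:5]}")
        logx = 2.0 + rng.normal(size=(len(roster), cfg.n_samples))
        if cfg.factor_groups:
            rho = float(cfg.factor_loading)
            if not 0.0 <= rho < 1.0:
                raise ValueError("factor_loading must be in [0, 1)")
            gene_pos = {g: i for i, g in enumerate(roster)}
            for name in sorted(cfg.factor_groups):
                factor = rng.normal(size=cfg.n_samples)
                for g in cfg.factor_groups[name]:
                    if g in gene_pos:
                        i = gene_pos[g]
                        logx[i] = 2.0 + rho * factor + np.sqrt(1 - rho**2) * (
                            (logx[i] - 2.0)
                        )
        expr = pd.DataFrame(
            np.exp(logx), index=roster,
            columns=[f"s{i + 1:04d}" for i in range(cfg.n_samples)],
        )

    logx = np.log1p(expr.to_numpy(dtype=float))
    mu = logx.mean(axis=1, keepdims=True)
    sd = logx.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (logx - mu) / sd
    eta = np.zeros(expr.shape[1])
    for g, coef in cfg.effect_genes.items():
        if g in expr.index:
            eta += coef * z[expr.index.get_loc(g)]
    lam = cfg.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    censor = np.full(expr.shape[1], cfg.censor_horizon)
    if cfg.early_censor_frac > 0:
        early = rng.random(expr.shape[1]) < cfg.early_censor_frac
        censor[early] = rng.uniform(0.0, cfg.censor_horizon, size=int(early.sum()))
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return SurvivalCohort(expr=expr, time=time, event=event)


@dataclass
class AtacSimConfig:
    n_peaks: int = 260
    n_cells: int = 1500
    cluster_props: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.25, "B": 0.30, "C": 0.20, "D": 0.25}
    )
    planted_se_genes: Sequence[str] = field(default_factory=list)
    planted_te_genes: Sequence[str] = field(default_factory=list)
    specific_peak_open_prob: float = 0.5
    background_open_prob: float = 0.05
    genome_length: int = 200_000_000
    seed: int = 0
    se_peaks_per_gene: int = 10
    te_peaks_max: int = 3
    peak_width: int = 500
    tss_spacing: int = 600_000
    peak_offset_step: int = 3_000

    def validate(self) -> None:
        _check_props(self.cluster_props, FIBRO_CLUSTERS, "cluster")
        if not self.specific_peak_open_prob > self.background_open_prob:
            raise ValueError("specific_peak_open_prob must exceed background")
        dup = set(self.planted_se_genes) & set(self.planted_te_genes)
        if dup:
            raise ValueError(f"genes planted as both SE and TE: {sorted(dup)[:5]}")


def _planted_offsets(k: int, step: int) -> list[int]:
    # alternating-side lattice around the TSS; spacing > peak width keeps
    # intervals non-overlapping and inside the 250 kb linkage window
    return [((j // 2) + 1) * step * (1 if j % 2 == 0 else -1) for j in range(k)]


def simulate_scatac(
    cfg: AtacSimConfig,
    cell_clusters: Sequence[str] | None = None,
) -> tuple[ad.AnnData, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Binary accessibility with planted Group-D-specific, TSS-proximal peaks.

    Returns ``(accessibility, peaks, tss, truth)``: a cells x peaks AnnData
    with per-cell ``cluster`` labels, a BED-convention peak table (0-based
    half-open, sorted by coordinate), a TSS table and the ground-truth
    peak-gene link list.  SE genes receive ``se_peaks_per_gene`` planted
    peaks, TE genes 1-3; planted peaks are open with
    ``specific_peak_open_prob`` in Group D cells and
    ``background_open_prob`` elsewhere; background peaks are uniformly open
    at the background rate.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = list(cfg.planted_se_genes) + list(cfg.planted_te_genes)

    if cell_clusters is not None:
        clusters = np.asarray(cell_clusters, dtype=object)
        if clusters.shape != (cfg.n_cells,):
            raise ValueError("cell_clusters must have length n_cells")
    else:
        p = _check_props(cfg.cluster_props, FIBRO_CLUSTERS, "cluster")
        clusters = rng.choice(FIBRO_CLUSTERS, size=cfg.n_cells, p=p)

    tss_rows = []
    peak_rows = []  # (start, end, gene or None)
    for i, g in enumerate(genes):
        tss = 1_000_000 + i * cfg.tss_spacing
        tss_rows.append((g, "chr1", tss, "+"))
        if g in cfg.planted_se_genes:
            k = cfg.se_peaks_per_gene
        else:
            k = int(rng.integers(1, cfg.te_peaks_max + 1))
        for off in _planted_offsets(k, cfg.peak_offset_step):
            start = tss + off - cfg.peak_width // 2
            peak_rows.append((start, start + cfg.peak_width, g))
    n_planted = len(peak_rows)
    if n_planted > cfg.n_peaks:
        raise ValueError(
            f"planted peak count {n_planted} exceeds n_peaks {cfg.n_peaks}"
        )
    bg_origin = 1_000_000 + len(genes) * cfg.tss_spacing + 1_000_000
    for j in range(cfg.n_peaks - n_planted):
        start = bg_origin + j * 2 * cfg.peak_width
        peak_rows.append((start, start + cfg.peak_width, None))
    if peak_rows and max(r[1] for r in peak_rows) > cfg.genome_length:
        raise ValueError("genome_length too small for the requested peaks")

    peak_rows.sort(key=lambda r: (r[0], r[1]))
    peaks = pd.DataFrame(
        {
            "peak_id": [f"peak_{i:05d}" for i in range(len(peak_rows))],
            "chrom": "chr1",
            "start": [r[0] for r in peak_rows],
            "end": [r[1] for r in peak_rows],
        }
    )
    truth = pd.DataFrame(
        [
            (f"peak_{i:05d}", r[2])
            for i, r in enumerate(peak_rows)
            if r[2] is not None
        ],
        columns=["peak_id", "gene"],
    )
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "tss_pos", "strand"])

    is_planted = np.array([r[2] is not None for r in peak_rows])
    is_d = clusters == "D"
    prob = np.full((cfg.n_cells, len(peak_rows)), cfg.background_open_prob)
    prob[np.ix_(is_d, is_planted)] = cfg.specific_peak_open_prob
    X = sp.csr_matrix(
        (rng.random(prob.shape) < prob).astype(np.int64)
    )
    obs = pd.DataFrame(
        {"cluster": pd.Categorical(clusters, categories=list(FIBRO_CLUSTERS))},
        index=[f"cell_{i:05d}" for i in range(cfg.n_cells)],
    )
    var = peaks.set_index("peak_id")
    adata = ad.AnnData(X=X, obs=obs, var=var)
    return adata, peaks, tss, truth
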