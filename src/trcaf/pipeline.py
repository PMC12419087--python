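"""End-to-end orchestration over synthetic data, with persisted intermediates.

The default run emulates the study design the pipeline was built for: a mixed
colorectal cell population whose fibroblasts carry four subclusters (A-D),
a tumor-restraining D cluster whose marker program is prognostically
protective, fibroblast-specific and PRRX1-low-enriched; a bulk survival
cohort with planted log-hazard effects on that program; and a paired
accessibility/expression dataset in which D-specific peaks drive a small set
of superenhancer genes.  Every stage writes its tables under the output
directory and the run report contains only numbers recomputable from them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .atac import (
    call_se_genes,
    compare_se_te_scores,
    count_qualifying_peaks,
    group_specific_peaks,
    peak_gene_links,
)
from .scoring import classify_high, module_score, proportion_shift
from .scrna import GeneSet, normalize, prrx1_refine, qc_filter, specificity_filter, wilcoxon_markers
from .simulate import (
    AtacSimConfig,
    ScrnaSimConfig,
    SurvivalSimConfig,
    simulate_scatac,
    simulate_scrna,
    simulate_survival_cohort,
)
from .survival import screen_genes, stratify_by_signature

__version__ = "0.1.0"
log = logging.getLogger("trcaf")

__all__ = [
    "RunConfig",
    "run_pipeline",
    "default_scrna_config",
    "default_survival_config",
    "default_atac_config",
    "planted_truth",
    "__version__",
]

# ---------------------------------------------------------------------------
# Planted ground truth of the default synthetic study
# ---------------------------------------------------------------------------

SE_GENES = (
    "ADAMDEC1", "CXCL14", "CCL8", "EMID1", "PRELP",
    "FENDRR", "GADD45G", "EDNRB", "PROCR", "CXCL12",
)
LR_EXTRA = tuple(f"DLR{i:02d}" for i in range(1, 6))       # protective, strong
TE_WEAK = tuple(f"DTE{i:02d}" for i in range(1, 26))       # D markers, weaker
A_MODULE = ("EBF1", "RSPO3", "GREM1") + tuple(f"AMK{i:02d}" for i in range(4, 11))
B_MODULE = ("PRRX1", "FAP") + tuple(f"BMK{i:02d}" for i in range(3, 11))
C_MODULE = ("ACTA2", "TAGLN", "MYH11", "ACTG2") + tuple(
    f"CMK{i:02d}" for i in range(5, 11)
)

RSTROMAL_TRUTH = SE_GENES + LR_EXTRA          # 15 planted protective D genes
ATAC_TE_TRUTH = LR_EXTRA + TE_WEAK            # 30 typical-enhancer genes
NONSPECIFIC_HR = tuple(f"G{i:04d}" for i in range(1, 3))
NONSPECIFIC_LR = tuple(f"G{i:04d}" for i in range(3, 5))


def planted_truth() -> dict:
    """Ground truth of the default synthetic study, for recovery tests."""
    return {
        "rstromal_lr": list(RSTROMAL_TRUTH),
        "stromal_hr": list(B_MODULE),
        "all_hr": list(B_MODULE) + list(NONSPECIFIC_HR),
        "all_lr": list(RSTROMAL_TRUTH) + list(NONSPECIFIC_LR),
        "se_genes": list(SE_GENES),
        "te_genes": list(ATAC_TE_TRUTH),
    }


def default_scrna_config(seed: int = 0, **overrides) -> ScrnaSimConfig:
    base = dict(
        n_genes=1000,
        n_cells=8000,
        cell_type_props={
            "epithelial": 0.30, "T": 0.25, "B": 0.10,
            "myeloid": 0.10, "fibroblast": 0.25,
        },
        marker_modules={
            "A": list(A_MODULE),
            # PRRX1 is the master TF of the tumor-promoting CAF state: low
            # baseline, sharply B-restricted, so the high/low dichotomy is
            # clean despite dropout
            "B": [g for g in B_MODULE if g != "PRRX1"],
            "B#prrx1": ["PRRX1"],
            "C": list(C_MODULE),
            "D#se": list(SE_GENES) + list(LR_EXTRA),
            "D#te": list(TE_WEAK),
        },
        marker_log_fc={
            "A": float(np.log(4)), "B": float(np.log(6)),
            "B#prrx1": float(np.log(12)),
            "C": float(np.log(4)), "D#se": float(np.log(6)),
            "D#te": float(np.log(3)),
        },
        gene_mean_overrides={"PRRX1": 0.2},
        seed=seed,
    )
    base.update(overrides)
    return ScrnaSimConfig(**base)


def default_survival_config(seed: int = 0, **overrides) -> SurvivalSimConfig:
    panel = (
        list(A_MODULE) + list(B_MODULE) + list(C_MODULE)
        + list(SE_GENES) + list(LR_EXTRA) + list(TE_WEAK)
    )
    panel += [f"G{i:04d}" for i in range(1, 301 - len(panel))]
    # planted programs are co-regulated (shared lognormal factor), so each
    # carries a program-level hazard effect with modest per-gene coefficients
    # and a strong marginal association per member gene
    effects: dict[str, float] = {}
    effects.update({g: -0.10 for g in RSTROMAL_TRUTH})
    effects.update({g: +0.15 for g in B_MODULE})
    effects.update({g: +0.6 for g in NONSPECIFIC_HR})
    effects.update({g: -0.6 for g in NONSPECIFIC_LR})
    base = dict(
        n_samples=300,
        baseline_hazard=0.1,
        censor_horizon=10.0,
        effect_genes=effects,
        gene_ids=panel,
        factor_groups={
            "rstromal_program": list(RSTROMAL_TRUTH),
            "b_program": list(B_MODULE),
        },
        factor_loading=0.9,
        seed=seed,
    )
    base.update(overrides)
    return SurvivalSimConfig(**base)


def default_atac_config(seed: int = 0, **overrides) -> AtacSimConfig:
    base = dict(
        n_peaks=260,
        n_cells=1500,
        planted_se_genes=list(SE_GENES),
        planted_te_genes=list(ATAC_TE_TRUTH),
        se_peaks_per_gene=10,
        seed=seed,
    )
    base.update(overrides)
    return AtacSimConfig(**base)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Effective configuration of a full run; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "trcaf_run"
    run_survival: bool = True
    run_scoring: bool = True
    run_proportions: bool = True
    run_atac: bool = True
    make_plots: bool = False
    log_level: str = "INFO"
    # QC / normalization
    qc_min_genes: int = 200
    qc_max_genes: int = 6000
    qc_min_umi: int = 1000
    qc_max_mito: float = 0.25
    scale_factor: float = 1e4
    # survival screen
    alpha: float = 0.05
    minprop: float = 0.1
    maxprop: float = 0.9
    p_method: str = "permutation"
    n_perm: int = 200
    # marker tests / refinement
    marker_q_cut: float = 0.05
    marker_lfc_cut: float = 0.25
    marker_min_pct: float = 0.1
    strat_gene: str = "PRRX1"
    # module scoring
    n_bins: int = 24
    n_ctrl: int = 100
    classify_method: str = "positive"
    # proportion shifts
    shift_test: str = "t"
    # SE calling
    link_window: int = 250_000
    metacell_k: int = 20
    r_cut: float = 0.45
    link_q_cut: float = 0.05
    peak_min_frac: float = 0.1
    peak_fold: float = 2.0
    peak_q_cut: float = 0.05
    # simulation overrides (passed into the default sim configs)
    scrna: Mapping = field(default_factory=dict)
    survival: Mapping = field(default_factory=dict)
    atac_sim: Mapping = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config YAML must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
        return wrapper
    return deco


def _derive_seeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute simulate -> screen -> refine -> score -> proportions ->
    se-call -> compare in dependency order, persisting every intermediate.

    Returns the run report (also written as report.json); identical config
    and seed reproduce byte-identical outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level.upper())
    seeds = _derive_seeds(cfg.seed)
    log.info("resolved config: %s", json.dumps(cfg.to_dict(), sort_keys=True, default=str))
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "derived_seeds": seeds,
        "gene_set_sizes": {},
        "statistics": {},
    }

    # --- simulate & preprocess single-cell data ---------------------------
    sc_cfg = default_scrna_config(seed=seeds[0], **dict(cfg.scrna))
    adata = _sim_scrna_stage(sc_cfg)
    tio.write_cell_matrix(adata, out / "sc_matrix")
    adata = qc_filter(
        adata, cfg.qc_min_genes, cfg.qc_max_genes, cfg.qc_min_umi, cfg.qc_max_mito
    )
    adata = normalize(adata, scale_factor=cfg.scale_factor)
    report["n_cells_post_qc"] = int(adata.n_obs)
    report["n_genes"] = int(adata.n_vars)

    fibro_markers = _markers_stage(
        adata, "cell_type", "fibroblast", cfg.marker_min_pct
    )
    fibro_markers.to_csv(out / "markers_fibroblast.tsv", sep="\t", index=False)
    fibro = adata[(adata.obs["cell_type"] == "fibroblast").to_numpy()].copy()

    gene_sets: list[GeneSet] = []

    if cfg.run_survival:
        surv_cfg = default_survival_config(seed=seeds[1], **dict(cfg.survival))
        cohort = _sim_survival_stage(surv_cfg)
        tio.write_clinical(cohort.samples, cohort.time, cohort.event, out / "clinical.tsv")
        tio.write_expression(cohort.expr, out / "expression.tsv")
        risk = _screen_stage(cohort, cfg, seeds[2])
        risk.to_csv(out / "gene_risk_table.tsv", sep="\t", index=False)
        all_hr = GeneSet.from_iterable(
            "All-HR", risk.loc[risk["risk_class"] == "ALL_HR", "gene"])
        all_lr = GeneSet.from_iterable(
            "All-LR", risk.loc[risk["risk_class"] == "ALL_LR", "gene"])
        stromal_hr, stromal_lr = specificity_filter(
            risk, fibro_markers, q_cut=cfg.marker_q_cut, lfc_cut=cfg.marker_lfc_cut
        )
        rstromal = prrx1_refine(
            fibro, stromal_lr, strat_gene=cfg.strat_gene,
            q_cut=cfg.marker_q_cut, lfc_cut=cfg.marker_lfc_cut,
            min_pct=cfg.marker_min_pct,
        )
        gene_sets += [all_hr, all_lr, stromal_hr, stromal_lr, rstromal]
        report["gene_set_sizes"].update(
            {
                "All-HR": len(all_hr), "All-LR": len(all_lr),
                "Stromal-HR": len(stromal_hr), "Stromal-LR": len(stromal_lr),
                "rStromal-LR": len(rstromal),
            }
        )
        if len(rstromal):
            labels, lr_res, (km_hi, km_lo) = stratify_by_signature(
                cohort, rstromal.genes, cut_method="maxstat",
                minprop=cfg.minprop, maxprop=cfg.maxprop,
                p_method=cfg.p_method, n_perm=cfg.n_perm, seed=seeds[3],
            )
            labels.to_frame().to_csv(out / "signature_labels.tsv", sep="\t")
            km = pd.concat(
                [km_hi.to_frame().assign(group="high"),
                 km_lo.to_frame().assign(group="low")]
            )
            km.to_csv(out / "km_rstromal.tsv", sep="\t", index=False)
            report["statistics"]["signature_logrank_p"] = lr_res.p_value
            if cfg.make_plots:
                from .plots import plot_km
                plot_km(km_hi, km_lo, out / "km_rstromal.png")

        if cfg.run_scoring and len(rstromal):
            scores = module_score(
                fibro, rstromal, n_bins=cfg.n_bins, n_ctrl=cfg.n_ctrl, seed=seeds[4]
            )
            flags = classify_high(scores, method=cfg.classify_method)
            pd.DataFrame(
                {"cell_id": list(scores.cell_ids), "score": scores.score,
                 "high": flags.to_numpy()}
            ).to_csv(out / "scores_rstromal.tsv", sep="\t", index=False)
            by_cluster = (
                pd.DataFrame({"cluster": fibro.obs["fibro_cluster"].astype(str).to_numpy(),
                              "score": scores.score})
                .groupby("cluster")["score"].mean()
            )
            report["statistics"]["mean_score_by_cluster"] = {
                k: float(v) for k, v in by_cluster.items()
            }

    if cfg.run_proportions:
        prop_table, shifts = proportion_shift(adata, test=cfg.shift_test)
        prop_table.to_csv(out / "proportions.tsv", sep="\t", index=False)
        shifts.to_csv(out / "proportion_shift.tsv", sep="\t", index=False)
        report["statistics"]["proportion_shift_p"] = {
            r["cluster"]: float(r["p_value"]) for _, r in shifts.iterrows()
        }

    if cfg.run_atac:
        atac_cfg = default_atac_config(seed=seeds[5], **dict(cfg.atac_sim))
        atac, peaks, tss, truth = simulate_scatac(atac_cfg)
        paired_cfg = _paired_expr_config(atac_cfg, seeds[6])
        paired = simulate_scrna(
            paired_cfg, fibro_clusters=atac.obs["cluster"].astype(str).to_numpy()
        )
        paired = normalize(paired, scale_factor=cfg.scale_factor)
        tio.write_bed(peaks, out / "peaks.bed")
        tio.write_tss(tss, out / "tss.tsv")
        truth.to_csv(out / "truth_links.tsv", sep="\t", index=False)
        peak_table = group_specific_peaks(
            atac, target="D", min_frac=cfg.peak_min_frac,
            fold=cfg.peak_fold, q_cut=cfg.peak_q_cut,
        )
        peak_table.to_csv(out / "peak_table.tsv", sep="\t", index=False)
        links = peak_gene_links(
            atac, paired, peaks, tss, window=cfg.link_window,
            metacell_k=cfg.metacell_k, r_cut=cfg.r_cut,
            q_cut=cfg.link_q_cut, seed=seeds[7],
        )
        links.to_csv(out / "links.tsv", sep="\t", index=False)
        qcounts = count_qualifying_peaks(links, peak_table)
        se_call = call_se_genes(qcounts)
        se_call.table.to_csv(out / "se_call.tsv", sep="\t", index=False)
        (out / "inflection.json").write_text(
            json.dumps({"inflection": se_call.inflection}, sort_keys=True) + "\n"
        )
        se, te = se_call.se_genes, se_call.te_genes
        tio.write_gmt([se, te], out / "se_te_sets.gmt")
        report["gene_set_sizes"].update({"SE": len(se), "TE": len(te)})
        if len(se) and len(te):
            cmp_df = compare_se_te_scores(
                paired, se, te, cluster_col="fibro_cluster",
                n_bins=cfg.n_bins, n_ctrl=cfg.n_ctrl, seed=seeds[4],
            )
            cmp_df.to_csv(out / "se_te_scores.tsv", sep="\t", index=False)
            report["statistics"]["se_te_delta"] = {
                r["cluster"]: {"delta": float(r["delta"]), "p": float(r["p_value"])}
                for _, r in cmp_df.iterrows()
            }
        if cfg.make_plots:
            from .plots import plot_elbow
            plot_elbow(se_call, out / "se_elbow.png")

    if gene_sets:
        tio.write_gmt(gene_sets, out / "genesets.gmt")

    with open(out / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n"
    )
    (out / "summary.txt").write_text(_summary_text(report))
    return report


@_stage("simulate_scrna")
def _sim_scrna_stage(cfg: ScrnaSimConfig):
    return simulate_scrna(cfg)


@_stage("simulate_survival")
def _sim_survival_stage(cfg: SurvivalSimConfig):
    return simulate_survival_cohort(cfg)


@_stage("markers")
def _markers_stage(adata, labels, group, min_pct):
    return wilcoxon_markers(adata, labels, group=group, min_pct=min_pct)


@_stage("screen")
def _screen_stage(cohort, cfg: RunConfig, seed: int):
    return screen_genes(
        cohort, alpha=cfg.alpha, minprop=cfg.minprop, maxprop=cfg.maxprop,
        p_method=cfg.p_method, n_perm=cfg.n_perm, seed=seed,
    )


def _paired_expr_config(atac_cfg: AtacSimConfig, seed: int) -> ScrnaSimConfig:
    """Expression roster paired with an accessibility simulation: SE genes are
    strong D markers, TE genes weaker, plus null filler genes."""
    se = list(atac_cfg.planted_se_genes)
    te = list(atac_cfg.planted_te_genes)
    n_genes = max(300, len(se) + len(te) + 200)
    return ScrnaSimConfig(
        n_genes=n_genes,
        n_cells=atac_cfg.n_cells,
        marker_modules={"D#se": se, "D#te": te},
        marker_log_fc={"D#se": float(np.log(6)), "D#te": float(np.log(3))},
        n_mito_genes=0,
        # markers sit mid-distribution so binned controls are null fillers,
        # not other planted markers
        marker_base_mean=2.0,
        seed=seed,
    )


def _summary_text(report: dict) -> str:
    lines = [f"trcaf run (version {report['version']}, seed {report['seed']})"]
    if report["gene_set_sizes"]:
        lines.append("gene set sizes:")
        for k, v in sorted(report["gene_set_sizes"].items()):
            lines.append(f"  {k}: {v}")
    stats = report["statistics"]
    if "signature_logrank_p" in stats:
        lines.append(
            f"signature stratification log-rank p = {stats['signature_logrank_p']:.3g}"
        )
    if "proportion_shift_p" in stats:
        pcs = ", ".join(f"{k}: {v:.3g}" for k, v in sorted(stats["proportion_shift_p"].items()))
        lines.append(f"cluster proportion shift p-values: {pcs}")
    if "se_te_delta" in stats:
        for k, v in sorted(stats["se_te_delta"].items()):
            lines.append(
                f"SE-TE module score delta in cluster {k}: {v['delta']:.4f} (p={v['p']:.3g})"
            )
    return "\n".join(lines) + "\n"
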