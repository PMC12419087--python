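"""Generate the synthetic study datasets.

Writes the mixed-population scRNA count matrix (with fibroblast clusters A-D
and planted marker programs), the bulk survival cohort whose hazard depends
on the planted rStromal and B programs, and the paired accessibility dataset
with Group-D-specific peaks, all under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, SEED

import trcaf.io as tio
from trcaf import simulate_scatac, simulate_scrna, simulate_survival_cohort
from trcaf.pipeline import (
    _paired_expr_config,
    default_atac_config,
    default_scrna_config,
    default_survival_config,
)


def main():
    sc_cfg = default_scrna_config(seed=SEED)
    adata = simulate_scrna(sc_cfg)
    tio.write_cell_matrix(adata, DATA / "sc_matrix")
    fib = (adata.obs["cell_type"] == "fibroblast").sum()
    print(f"scRNA: {adata.n_obs} cells x {adata.n_vars} genes "
          f"({fib} fibroblasts, {adata.obs['sample'].nunique()} samples)")

    cohort = simulate_survival_cohort(default_survival_config(seed=SEED + 1))
    tio.write_clinical(cohort.samples, cohort.time, cohort.event,
                       DATA / "clinical.tsv")
    tio.write_expression(cohort.expr, DATA / "expression.tsv")
    print(f"survival cohort: {len(cohort.samples)} samples, "
          f"{len(cohort.genes)} genes, event rate {cohort.event.mean():.2f}")

    atac_cfg = default_atac_config(seed=SEED + 2)
    atac, peaks, tss, truth = simulate_scatac(atac_cfg)
    tio.write_cell_matrix(atac, DATA / "atac_matrix")
    tio.write_bed(peaks, DATA / "peaks.bed")
    tio.write_tss(tss, DATA / "tss.tsv")
    truth.to_csv(DATA / "truth_links.tsv", sep="\t", index=False)
    paired = simulate_scrna(
        _paired_expr_config(atac_cfg, SEED + 3),
        fibro_clusters=atac.obs["cluster"].astype(str).to_numpy(),
    )
    tio.write_cell_matrix(paired, DATA / "paired_expr_matrix")
    print(f"scATAC: {atac.n_obs} cells x {atac.n_vars} peaks, "
          f"{len(truth)} ground-truth peak-gene links")


if __name__ == "__main__":
    main()
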