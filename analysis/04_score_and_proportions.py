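"""Module scoring of the refined signature and cluster-proportion shifts.

Scores every fibroblast for the rStromal-LR set (binned-control module
score), flags score-high cells, and tests per-sample fibroblast cluster
fractions between normal and tumor samples (Welch t).  Also stratifies the
bulk cohort by the signature and reports the log-rank p-value.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, OUT, SEED

import trcaf.io as tio
from trcaf import SurvivalCohort, stratify_by_signature
from trcaf.scoring import classify_high, module_score, proportion_shift
from trcaf.scrna import normalize, qc_filter


def main():
    m = tio.read_cell_matrix(
        DATA / "sc_matrix/matrix.mtx", DATA / "sc_matrix/features.tsv",
        DATA / "sc_matrix/barcodes.tsv", meta_path=DATA / "sc_matrix/cell_meta.tsv",
    )
    m = normalize(qc_filter(m))
    fibro = m[(m.obs["cell_type"] == "fibroblast").to_numpy()].copy()

    rstromal = next(s for s in tio.read_gmt(OUT / "genesets.gmt")
                    if s.name == "rStromal-LR")
    scores = module_score(fibro, rstromal, seed=SEED)
    flags = classify_high(scores)
    pd.DataFrame({"cell_id": list(scores.cell_ids), "score": scores.score,
                  "high": flags.to_numpy()}
                 ).to_csv(OUT / "scores_rstromal.tsv", sep="\t", index=False)
    by_cluster = (
        pd.DataFrame({"cluster": fibro.obs["fibro_cluster"].astype(str).to_numpy(),
                      "score": scores.score})
        .groupby("cluster")["score"].mean()
    )
    print("mean rStromal-LR score by cluster:")
    print(by_cluster.round(3).to_string())

    table, shifts = proportion_shift(m)
    table.to_csv(OUT / "proportions.tsv", sep="\t", index=False)
    shifts.to_csv(OUT / "proportion_shift.tsv", sep="\t", index=False)
    print("\ncluster proportion shifts (normal vs tumor):")
    print(shifts.round(4).to_string(index=False))

    clin = tio.read_clinical(DATA / "clinical.tsv")
    expr = tio.read_expression(DATA / "expression.tsv")[clin["sample_id"]]
    cohort = SurvivalCohort(expr=expr, time=clin["time"].to_numpy(),
                            event=clin["event"].to_numpy())
    labels, lr, (km_hi, km_lo) = stratify_by_signature(
        cohort, rstromal.genes, cut_method="maxstat",
        p_method="permutation", n_perm=200, seed=SEED,
    )
    km = pd.concat([km_hi.to_frame().assign(group="high"),
                    km_lo.to_frame().assign(group="low")])
    km.to_csv(OUT / "km_rstromal.tsv", sep="\t", index=False)
    print(f"\nsignature stratification log-rank p = {lr.p_value:.3g} "
          f"(high group: {(labels == 'high').sum()} samples)")


if __name__ == "__main__":
    main()
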