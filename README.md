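# trcaf

Discovery pipeline for **tumor-restraining cancer-associated fibroblast
(Tr-CAF) gene programs** in colorectal cancer, rebuilt as a tested,
fully synthetic-data-driven Python package.

Colorectal stroma contains fibroblast subpopulations with opposite effects
on tumor progression. The analysis this package implements identifies the
protective program in three moves, then corroborates it epigenetically:

1. **Survival screen.** For each gene *g* of a bulk RNA-seq cohort with
   right-censored follow-up, patients are split at the expression cutpoint
   μ* maximizing the standardized log-rank statistic (maximally selected
   rank statistic) — μ* = argmax |O₁−E₁|/√V over admissible cutpoints —
   with a permutation p-value that accounts for the cutpoint selection and
   the Pike hazard-ratio estimate HR = (O₁/E₁)/(O₂/E₂). Genes with p < 0.05
   split into **All-HR** (HR > 1) and **All-LR** (HR < 1).
2. **Single-cell refinement.** Risk genes are kept only if they are
   significant positive Wilcoxon markers of fibroblasts
   (**Stromal-HR/LR**); Stromal-LR genes additionally enriched in
   PRRX1-low fibroblasts (PRRX1 marks the tumor-promoting CAF state) form
   the refined protective set **rStromal-LR**.
3. **Cell-level validation.** Each fibroblast gets a binned-control module
   score, score = mean(set) − mean(expression-matched controls); per-sample
   cluster proportions are compared between normal and tumor tissue
   (Welch t), and the cohort is re-stratified by the signature
   (Kaplan–Meier + log-rank).
4. **Superenhancer caller (scATAC).** Peaks unique to the protective
   fibroblast group (Group D) that correlate with gene expression across
   metacells (Pearson r ≥ 0.45, BH q < 0.05, ≤250 kb from the TSS) are
   counted per gene; the ranked, [0,1]-scaled count curve is split at its
   slope-1 inflection, ROSE-style: genes above are **SE-driven**, below
   **TE-driven**.

A seeded synthetic-data module generates every input with the statistical
structure the pipeline assumes (negative-binomial scRNA counts with planted
fibroblast clusters A–D, a proportional-hazards cohort with planted gene
programs, Bernoulli accessibility with planted Group-D peaks), so the whole
pipeline runs and is tested with no downloads. See `docs/methods.md` for
the model details and design choices.

## Worked example

The numbered drivers under `analysis/` run the study end to end on the
default synthetic conditions and write their tables under `results/`:

```bash
python analysis/01_simulate_data.py
python analysis/02_survival_screen.py
python analysis/03_refine_gene_sets.py
python analysis/04_score_and_proportions.py
python analysis/05_se_calling.py
```

Output of the run (seed 1):

```
scRNA: 8000 cells x 1000 genes (2017 fibroblasts, 16 samples)
survival cohort: 300 samples, 300 genes, event rate 0.60

screened 300 genes: 14 All-HR, 23 All-LR
planted rStromal program recovered in All-LR: 15/15

Stromal-HR 10, Stromal-LR 15, rStromal-LR 15
planted rStromal genes recovered: 15/15; false positives: 0

mean rStromal-LR score by cluster:
A   -0.333   B   -0.281   C   -0.253   D    0.986

cluster proportion shifts (normal vs tumor):
cluster  mean_normal  mean_tumor  p_value
      A       0.3743      0.1547   0.0000
      B       0.1008      0.4980   0.0000
      C       0.1967      0.1925   0.8011
      D       0.3282      0.1548   0.0000

signature stratification log-rank p = 1.41e-18

SE genes: 10 (planted recovered 10/10), TE genes: 30
SE vs TE module score delta in cluster D: +0.84 (p < 1e-10), negative elsewhere
```

Reading: the screen recovers the planted protective program among the
All-LR genes; the specificity and PRRX1 filters strip the non-fibroblast
and non-protective genes, leaving exactly the 15 planted rStromal-LR genes;
the module score singles out cluster D (the putative Tr-CAF population),
whose proportion drops in tumor tissue while cluster B (tumor-promoting
CAFs) expands; and the SE caller recovers the 10 planted
superenhancer-driven genes, which are preferentially enriched in cluster D.

The same pipeline is available as one orchestrated command:

```bash
trcaf run --seed 1 --out results/run    # writes report.json + summary.txt
```

with stage-level subcommands (`trcaf simulate|qc|markers|screen|refine|
score|proportions|se-call`) for file-based use.

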