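# Methods

## Scope and model of the analysis

The package re-implements, as a tested pipeline over synthetic data, the
computational procedure for discovering a tumor-restraining fibroblast
subpopulation in colorectal cancer:

1. **Per-gene survival screen.** Each gene of a bulk cohort is dichotomized
   at the expression cutpoint that maximizes a standardized two-group
   log-rank statistic (a maximally selected rank statistic). Genes with a
   selection-adjusted p < α and Pike hazard ratio > 1 are classified
   high-risk (All-HR); HR < 1 low-risk (All-LR).
2. **Fibroblast-specificity filter.** Risk genes are restricted to
   significant positive rank-sum markers of the fibroblast cell type in a
   single-cell dataset (Stromal-HR / Stromal-LR).
3. **PRRX1-low refinement.** Fibroblasts are split by PRRX1 expression
   (nonzero vs zero normalized counts, a dropout-tolerant proxy for the
   tumor-promoting CAF state); Stromal-LR genes significantly enriched in
   the PRRX1-low stratum form the refined rStromal-LR set.
4. **Module scoring and proportion shifts.** Cells are scored for a gene set
   by the binned-control module score (mean set expression minus mean of
   expression-matched controls); per-sample fibroblast cluster fractions are
   compared between normal and tumor samples with a two-sided Welch t test.
5. **Superenhancer-driven gene calling.** Accessibility peaks unique to the
   target fibroblast group and significantly correlated with gene expression
   across metacells are counted per gene; genes are ranked by qualifying-peak
   count and split at the slope-1 inflection of the scaled rank curve
   (ROSE-style): above = SE-driven, below = TE-driven.

## Survival statistics

* **Kaplan–Meier** estimation delegates to `lifelines`; log-rank and maxstat
  are implemented in-package because they must expose per-group
  observed/expected counts (for the Pike estimator (O₁/E₁)/(O₂/E₂)) and
  per-cutpoint standardized statistics. `lifelines` remains the independent
  cross-check in the tests.
* **Variance convention.** The maxstat scan standardizes O₁−E₁ with the
  Mantel–Cox hypergeometric variance at each dichotomy, so the squared
  standardized statistic at a fixed cutpoint equals the ordinary log-rank
  chi-square there. (The alternative convention standardizes with the
  permutation variance of the linear rank statistic; the two differ by
  O(1/n) and the hypergeometric choice makes the log-rank/maxstat
  equivalence exact.)
* **Cutpoint scan.** Every distinct expression value whose induced low-group
  proportion lies in [minprop, maxprop] (defaults 0.1/0.9, the convention of
  maximally-selected-statistic software) is scanned; the reported cutpoint
  is the midpoint between the two adjacent distinct values bracketing the
  best split, with ties resolved toward the smallest cutpoint for
  determinism.
* **Selection-adjusted p-values.** Default is a permutation test of the
  maximal statistic (n_perm = 1000 at the API level; the orchestrated run
  uses 200): expression is permuted against (time, event), which reduces to
  scanning prefixes of random sample orderings, vectorized over permutation
  batches. The p-value is add-one smoothed. A sequential early stop
  (default: after 25 exceedances) truncates permutations for genes that can
  no longer reach α = 0.05; truncated estimates stay valid (and only arise
  above p ≈ 0.1), while small p-values always use the full budget. The
  Brownian-bridge band-crossing approximation is offered as a fast
  alternative; it is conservative at small n, which is why the permutation
  test is the default.
* The post-hoc log-rank p at the chosen cutpoint is deliberately **not**
  used for classification: it ignores cutpoint selection and is
  anti-conservative; classification uses the selection-adjusted p at a
  nominal α = 0.05, with BH q-values reported alongside for reference.

## Single-cell processing

* QC keeps cells with >200 and <6000 detected genes, >1000 total counts and
  mitochondrial fraction ≤ 0.25 (strict inequalities as stated). The gene
  roster is never changed by QC.
* Normalization is log(1 + s·count/total) with s = 10⁴ (the default of the
  standard normalization routine).
* Variable genes use the classic mean/dispersion method: on back-scaled
  (expm1) data, dispersion = variance/mean, z-standardized within 20
  equal-width bins of log1p(mean); genes in the window
  0.0125 < log1p(mean) < 3 with standardized dispersion > 0.5 are ranked
  and the top n taken. `scanpy`'s seurat-flavor implementation is the
  cross-check oracle in the tests.
* Marker testing is a two-sided Wilcoxon rank-sum on normalized values via
  `scipy.stats.mannwhitneyu(method="auto")`: exact for small tie-free
  groups (which is what the brute-force enumeration oracle checks),
  tie-corrected normal approximation otherwise. Fold changes are natural-log
  of (mean expm1 + 1) ratios; genes detected in <10% of both groups are not
  tested; BH correction is applied over tested genes.
* "Specifically expressed in fibroblasts" is operationalized as significant
  positive fibroblast marker status (q < 0.05, log-FC > 0.25); a stricter
  mode additionally excludes genes that are significant markers of any
  other supplied cell type.

## Module scores and proportion tests

Genes are ordered by (dataset-average normalized expression, gene id) —
the deterministic secondary key makes scores invariant to the storage order
of genes — and cut into 24 equal-frequency bins. Each set gene draws 100
controls from its bin excluding set genes (with replacement if the pool is
smaller; if a bin holds only set genes the whole bin is used, so the
all-genes set scores ≈ 0). Score-high cells default to score > 0; a
quantile rule (ties broken by cell id) is available. Cluster fractions are
computed among fibroblasts only and tested per cluster across samples with
Welch t (default) or rank-sum.

## SE caller

* **Group specificity**: detection fraction in the target cluster ≥ 0.1,
  ≥ 2× the maximum fraction of any other cluster, and a two-proportion z
  test (target vs rest) with BH q < 0.05. The fraction-fold + test
  combination operationalizes "unique to the group"; no single formula is
  canonical.
* **Linkage**: cells are partitioned within each cluster into seeded random
  metacells of size 20 (a random partition avoids importing an embedding;
  KNN metacells are out of scope). For every (peak, gene) pair with peak
  midpoint within 250 kb of the TSS, the Pearson correlation of
  metacell-mean log-normalized accessibility and expression is tested
  (t distribution, df = metacells − 2), BH-adjusted across all tested
  pairs; links need r ≥ 0.45 and q < 0.05. Only positively correlated links
  qualify by default (enhancer logic); anti-correlated links can be enabled.
* **Elbow**: genes sorted ascending by (count, gene id); both axes scaled to
  [0, 1]; slope via centered differences over a 5-point window (clamped at
  the edges) to suppress step noise from integer counts. Scanning left to
  right, the rightmost upward crossing of slope 1 defines the inflection,
  placed at the last point on the slope ≤ 1 side; SE genes are strictly
  above it, so cutoff ties fall to TE (a conservative, deterministic SE
  set). If the slope never crosses 1 upward (flat or purely linear curves)
  no gene is called SE. Zero dynamic range yields all-TE with a warning.
* Gene rank uses the qualifying-peak **count** (distinct specific linked
  peaks); a summed-correlation alternative was considered and rejected as
  the ranked quantity because the count is the stated ranking currency of
  the procedure; the links table retains per-pair r so a summed variant can
  be computed from the outputs.

## Synthetic data: what it emulates and what it does not

* **scRNA counts** are gamma–Poisson (negative binomial, dispersion 0.5)
  with lognormal library sizes around 4000 counts/cell — the standard scRNA
  noise model matching the downstream normalization assumptions. Cell types
  follow fixed proportions; fibroblasts carry clusters A–D with
  condition-dependent proportions (B expands in tumor, A and D shrink).
  Marker modules multiply the module genes' means by exp(log-FC) in their
  target population; module keys may carry a `#tag` suffix so several
  disjoint modules can target one cluster with different fold changes.
  Module genes receive a fixed base mean (0.5 counts/cell in the main
  dataset; 2.0 in the accessibility-paired dataset so markers sit
  mid-distribution and their binned controls are null fillers) rather than
  a lognormal draw, so planted effect sizes are controlled, not lottery
  outcomes. PRRX1 is planted as a sharply B-restricted, low-baseline gene
  (log-FC ln 12, base mean 0.2), reflecting its role as the defining TF of
  the tumor-promoting CAF state and giving a clean nonzero/zero dichotomy
  under dropout.
* **Survival cohorts** draw exponential event times with hazard
  h₀·exp(Σ coef·z) (z = per-gene z-score of log1p expression) and
  administrative censoring at a fixed horizon (defaults h₀ = 0.1, horizon
  10 → ≈60% events), plus optional uniform early censoring. Planted
  programs are modeled as co-regulated gene groups sharing a lognormal
  latent factor (loading 0.9) with modest per-gene coefficients (−0.10 per
  rStromal gene, +0.15 per B-program gene), so each member gene carries a
  strong marginal association while the total log-hazard spread stays
  realistic (sd ≈ 2). Planting many independent strong effects instead
  creates a frailty-like attenuation of every marginal effect — a property
  of the additive hazard model worth knowing when designing recovery
  experiments (the recovery analyses therefore plant at most six
  independent effects per cohort).
* **Accessibility** is Bernoulli per (cell, peak): planted peaks open with
  probability 0.5 in Group D and 0.05 elsewhere; background peaks 0.05
  everywhere. SE genes get 10 planted peaks, TE genes 1–3, placed on an
  alternating-side lattice (3 kb steps) within the linkage window of their
  gene's TSS on a synthetic chromosome; coordinates are 0-based half-open
  and round-trip through BED bit-exactly. The generator returns the
  ground-truth link list for recovery tests.
* Not emulated: doublets, ambient RNA, batch effects, realistic genome
  annotation, chromatin co-accessibility beyond the planted cluster
  structure, and informative censoring. Passing tests therefore demonstrate
  the statistical machinery under the stated generative assumptions, not
  robustness to these real-data artifacts.
* Every generator draws from a single `numpy` generator seeded from its
  config; identical configs reproduce bit-identical outputs.

## Problem sizes of the shipped analyses

The orchestrated run and the acceptance analyses use: 8000 cells × 1000
genes (≈2000 fibroblasts, 8 samples per condition), a 300-sample ×
300-gene survival panel screened with 200 permutations, and 1500 cells ×
260 peaks for the accessibility stage. Null calibrations use 1000 null
genes at n = 100 samples (screen), 600–1200 replicate two-arm designs of 10
samples × 60 cells (proportion test), and ~800 independent null peak–gene
pairs (linkage). These sizes were chosen as the smallest designs that give
stable rates and high-powered recovery of the planted effects.

## Numerical and degenerate-input choices

* Permutation batches use float32 (the observed scan float64); the
  exceedance comparison carries a 10⁻⁵ tolerance so float32 rounding cannot
  flip a count.
* Genes with all-tied expression (no admissible cutpoint) are flagged and
  classified NONE; a Pike HR with a zero expected count is NaN; a log-rank
  variance of zero yields statistic 0, p 1.
* Zero-count cells are dropped at normalization (with a warning); in the
  two-modality linkage path they are instead kept as zero rows so the
  modalities stay cell-aligned.
* Identical SE/TE input sets produce a delta of exactly 0 because both sets
  are scored with the same control-sampling seed.

## Known limitations

* The screen treats genes marginally; no multivariable adjustment or Cox
  modeling (out of scope by design — the procedure's rule is
  HR-direction + nominal α).
* The permutation p-value's resolution is 1/(n_perm+1); with the default
  orchestrated run (200 permutations) the smallest attainable p is ≈0.005.
* Metacell partitioning is random within cluster; correlations are
  therefore driven by between-cluster structure plus within-cluster
  sampling noise, which is the intended regime of the planted designs but
  weaker than KNN-based aggregation for continuous gradients.
* The elbow rule assumes the count distribution is either clearly elbowed
  or degenerate; adversarial multi-elbow curves resolve to the rightmost
  crossing (conservative SE set).
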