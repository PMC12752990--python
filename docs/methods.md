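# Methods

`dmrkit` analyses whole-genome bisulfite sequencing (WGBS) of blood from a
case/control cohort (diseased dogs versus healthy controls) to discover
differentially methylated regions (DMRs) and to build predictive models from
them. This document describes the statistical models, the synthetic cohort
generator used for testing, the numerical choices, and the known limitations.

## Data model

The primary input is a per-CpG count matrix: for each CpG site (chromosome,
1-based position) and each sample, the number of methylated read calls and the
total read calls. Per-site methylation level ("beta") is
`methylated / total`, expressed in percentage points (pp, 0–100) where noted.
Strand-split call files are destranded on load: a minus-strand cytosine at
position `p` is folded onto the plus-strand CpG at `p − 1` and counts are
summed. A sample sheet carries group labels (`case` / `control`), covariates
(breed, age, sex, steroid exposure, clinical setting), and an optional
train/test split assignment.

## Quality control

- **Coverage filter.** A CpG is kept only if every sample covers it with at
  least `min_cov` reads and at most `max_cov` reads (defaults 10 and 500,
  inclusive on both boundaries). The lower bound controls binomial noise in
  beta estimates; the upper bound removes collapsed repeats and PCR artefacts.
- **PCA.** Principal components of the centred/scaled beta matrix over the
  filtered sites, for visual inspection of batch and group structure.
- **PVCA.** Principal-variance-component analysis: the variance of each
  retained principal component (those covering a cumulative variance
  threshold, default 0.6) is attributed to sample factors with a random-effects
  fit per component; fractions are weighted by the component eigenvalues and
  renormalised together with a residual so they sum to 1. Single-level factors
  contribute 0 with a warning.
- **Sequencing summary.** Per-sample sequencing statistics are averaged per
  cohort. Report rounding uses decimal **half-up** rounding (0.5 rounds away
  from zero) rather than the banker's rounding of IEEE floats, because cohort
  means of read counts frequently land exactly on a half boundary and the
  conventional presentation in sequencing reports is half-up.

## Differential methylation

### Per-CpG test

Each CpG is tested with a binomial logistic regression of methylated counts on
the group label plus covariates (defaults: breed and age). Breeds are pooled
into an `other` level when rarer than the pooling threshold so the design stays
full rank in small cohorts. The model is fit by iteratively reweighted least
squares, vectorised across all sites at once. The group effect is assessed by
a likelihood-ratio test against the covariate-only model (chi-squared, 1 df).
P-values are adjusted with Benjamini–Hochberg. A site is a **DMC**
(differentially methylated cytosine) when `q < 0.05` **and** the absolute
difference of unweighted per-sample mean betas between groups exceeds 10 pp.

### Permutation-null filter

To suppress sites that reach significance under arbitrary label assignments,
the group labels are shuffled `n_perm` times (default 100) and the full
genome-wide DMC call is repeated per shuffle; the covariate-only null deviance
does not depend on labels and is fit once and reused. A candidate DMC is
discarded if it is re-called in more than `max_hits` permutations (default 1).

**Behavioural caveat.** With small, balanced groups, a random shuffle
frequently reproduces the true labels almost exactly, so genuinely strong
effects are re-called under permutation and the filter removes *true*
positives. The effect worsens as the planted effect grows. This is an
inherent property of the published procedure, not an implementation artefact;
the synthetic-cohort tests quantify it, and pipeline users with small cohorts
should expect low sensitivity at `max_hits = 1`.

### DMR construction

Retained DMCs are merged by single-linkage chaining: consecutive DMCs on the
same chromosome at most `gap` bp apart (default 100, inclusive) join a region;
regions with fewer than `min_dmcs` members (default 6) are dropped. The
region direction is the majority sign of member effects (ties → `mixed`).

### Confounder subtraction and censoring

Corticosteroid exposure alters blood methylation independently of disease.
Confounded regions are called with the same machinery but contrasting the
steroid flag, deliberately looser: no covariate adjustment and `min_dmcs = 4`.
Any candidate DMR overlapping a confounder region by ≥ 1 bp is removed, then
whole sex chromosomes (`chrX`) are censored. If the steroid contrast is
correlated with the disease label (as it is in clinical cohorts where cases
receive steroids), this subtraction also removes genuinely disease-associated
regions; this trade-off is intentional and favours specificity.

## Region summaries, clustering, and enrichment

- **Region beta.** The unweighted mean of member-CpG betas per sample.
- **K-means.** Regions are clustered on their per-sample beta profiles with
  k-means; labels are reindexed by decreasing cluster size for determinism,
  and nested restarts guarantee the within-cluster sum of squares (WCSS) is
  monotone non-increasing in `k`. The elbow suggestion picks the smallest `k`
  after which the relative WCSS drop falls below 0.1; this heuristic is
  reliable only for well-separated, comparably loose clusters.
- **Gene mapping.** A region maps to a gene by (in priority order) any-base
  **overlap**; strand-aware **promoter** hit, where the promoter is
  `[TSS − 1500, TSS − 1]` for plus-strand genes and `[end + 1, end + 1500]`
  for minus-strand genes; or **within_adjacent**, the nearest gene within
  10 kb (distance ties broken lexically by gene id, or reported in full with
  `report_ties=True`). Genes with unknown strand are excluded from promoter
  calls with a warning.
- **Enrichment.** Term enrichment uses the exact hypergeometric upper tail
  `P(X ≥ k)` (survival function at `k − 1`) over the mapped-gene background,
  with BH adjustment across terms.

## Predictive models

All models are trained on the training split only; evaluation helpers refuse
sample overlap between train and test ids.

### Single-region screen

Each region's beta is scored by a one-dimensional logistic fit. Regions are
screened with a stratified bootstrap: the same in-bag resamples (drawn with
replacement within each class) are shared across regions so rankings are
comparable; out-of-bag AUROC quantiles give a confidence interval, reported as
`(-, -)` when a resample is degenerate. AUROC is the tie-aware (weighted)
Mann–Whitney statistic; AUPRC is the step-integrated average precision with
tie blocks handled jointly.

### Sparse multi-region model (L0L2 logistic regression)

The multi-region classifier minimises

```
sum_i log(1 + exp(eta_i)) − y_i eta_i + gamma ||beta||² + lambda ||beta||₀
```

by majorised cyclic coordinate descent with hard thresholding (the objective
is asserted non-increasing across sweeps), followed by a local search over
support moves: single-feature drop/add/swap, and — only when no single move
improves — pairwise add/drop moves, each scored by an exact ridge-logistic
Newton refit. Pair moves matter because two jointly informative features can
be unable to enter the support one at a time at large `lambda`.
`lambda_max` (the smallest penalty at which the empty support is optimal) is
derived from the intercept-only fit; the grid is geometric below it. `lambda`
is chosen by stratified k-fold cross-validation on validation log-loss, with
ties resolved toward the larger penalty (sparser model). The ridge refit is
numerically equivalent to scikit-learn's `LogisticRegression` with
`C = 1 / (2·gamma)`.

### Tree-per-cluster forest

As an alternative panel selector, a shallow decision tree is fit within each
k-means cluster of regions; the regions each tree actually splits on form the
panel, and a random forest is trained on the pooled panel.

## Pipeline orchestration

`run_pipeline` chains: hold-out split → coverage filter (training samples) →
DMC call → permutation filter → DMR merge → steroid-confounder subtraction and
chrX censoring → region betas → clustering → gene mapping/enrichment (when
annotations are supplied) → single-region screen → sparse and forest models →
held-out evaluation. Every artefact is written to the run directory with a
SHA-256 checksum recorded in `manifest.json` together with a hash of the full
configuration; identical inputs and configuration produce byte-identical
outputs. Stage failures raise errors naming the stage, and artefacts written
before the failure persist for debugging. Discovery uses only training
samples; corrupting held-out samples provably leaves discovery checksums
unchanged (tested).

## Synthetic cohort generator

`simulate_cohort` emulates a blood WGBS case/control cohort for testing:

- CpG positions are scattered over several autosomes plus `chrX` with
  realistic local clustering; per-site coverage is drawn around a mean of ~70×
  with overdispersion, and counts are binomial given the per-site, per-sample
  methylation probability.
- Baseline methylation per site is drawn from a bimodal distribution (mostly
  near-0 or near-1, as in real methylomes).
- **Disease regions**: contiguous blocks of 6–8 CpGs whose methylation
  probability is shifted by `delta_beta` (probability scale, clipped to
  [0.01, 0.99]) in cases, with **region-coherent noise**: a shared per-sample,
  per-region Gaussian wobble on top of binomial sampling, so member CpGs
  co-vary as they do in real data.
- **Steroid regions**: analogous blocks shifted in steroid-exposed samples
  (default effect 0.15); steroid prevalence defaults to 0.45 in cases versus
  0.15 in controls, reproducing the clinical confounding.
- `chrX` carries a sex effect; demographics (breed, age, sex, setting) are
  sampled per group.

Scope and limits: the generator produces valid destranded count matrices with
planted ground truth sufficient to exercise every pipeline stage. It does not
model read-level error, bisulfite non-conversion, copy-number variation,
cell-composition shifts, or genome-wide autocorrelation beyond the planted
regions, so absolute sensitivity numbers on synthetic cohorts should not be
read as field performance.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` seeded explicitly;
  derived child seeds stay below 2³¹.
- Batched IRLS clips fitted probabilities away from 0/1 for stable weights;
  the per-site LRT is validated against `statsmodels` GLM fits to 1e-5.
- BH adjustment preserves the input order of p-values.
- Half-up rounding for report tables uses `decimal` on the shortest-repr of
  the float, avoiding double-rounding artefacts.
- Interval operations (merge, overlap subtraction, promoter windows) are
  bespoke and inclusive-boundary by specification; BED output converts to the
  conventional 0-based half-open coordinates.

## Acceptance-scale checks

The acceptance tests and `scripts/acceptance.py` run the chain at realistic
sizes: 20 000 CpGs per cohort, 100-permutation filters, null specificity over
replicate cohorts, exhaustive best-subset oracles over 2¹⁰ supports, exact
rational hypergeometric enumeration for all backgrounds up to 25 genes, and
held-out AUROC of both multi-region models on planted cohorts with a
16 + 12 training / 4 + 7 test split.

## Limitations

- The permutation-null filter's sensitivity collapse in small balanced cohorts
  (see above) means planted-region recovery at `max_hits = 1` can be far below
  1 even for clean 15 pp effects; this is faithfully reproduced, not patched.
- The elbow heuristic under- or over-suggests `k` when clusters have very
  different within-cluster spreads.
- PVCA uses a moment-style random-effects attribution per component, not a
  full REML mixed model across all components jointly.
- The generator's coverage and baseline distributions are stylised; tests
  anchored to it validate mechanics and relative behaviour, not absolute
  clinical performance.
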