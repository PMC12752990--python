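# dmrkit

Case/control analysis of blood whole-genome bisulfite sequencing (WGBS):
discovery of differentially methylated regions (DMRs) with a permutation-null
filter and confounder subtraction, followed by held-out predictive modeling.

## The problem

Blood is an attractive liquid-biopsy substrate for diagnosing disease from DNA
methylation, but blood WGBS in small clinical cohorts is hostile territory:
per-CpG counts are noisy binomials, breed/age/sex structure confounds the
case/control contrast, corticosteroid treatment of cases reshapes blood
methylation independently of the disease, and any marker panel selected on the
same animals it is evaluated on will look better than it is.

`dmrkit` implements a complete discovery-to-prediction chain that addresses
each of these:

1. **QC** — inclusive coverage filtering (every sample ≥ 10× and ≤ 500× at a
   site), PCA, and principal-variance-component analysis (PVCA) to attribute
   variance to sample factors.
2. **DMC calling** — per-CpG binomial logistic regression with covariate
   adjustment (breed, age), likelihood-ratio tests, Benjamini–Hochberg
   correction; a site is differentially methylated when `q < 0.05` and the
   group beta difference exceeds 10 percentage points.
3. **Permutation-null filter** — the genome-wide call is repeated under label
   shuffles; candidates that recur under more than `max_hits` shuffles are
   discarded.
4. **DMR construction** — chaining of DMCs ≤ 100 bp apart, keeping regions
   with ≥ 6 members; steroid-confounded regions (called looser: no covariates,
   ≥ 4 members) are subtracted by any-base overlap and chrX is censored.
5. **Downstream** — region-level methylation, k-means clustering with a WCSS
   elbow, strand-aware gene mapping, hypergeometric term enrichment.
6. **Prediction** — single-region bootstrap screening (AUROC/AUPRC), a sparse
   L0L2-penalized logistic model solved by coordinate descent with exhaustive-
   quality local search, and a tree-per-cluster random-forest panel; all
   trained on the training split and evaluated on held-out samples with
   leakage guards.

A synthetic cohort generator (`simulate_cohort`) plants disease regions,
steroid-confounded regions, and sex effects into realistic count matrices and
is itself a tested, first-class part of the package. See
[docs/methods.md](docs/methods.md) for the full model descriptions.

## Run the tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests, seeded property-based tests (hypothesis), and
an acceptance suite (`tests/test_acceptance.py`) that runs at realistic
problem sizes (the acceptance suite alone takes ~16 minutes on one CPU). One
acceptance test — planted-region recovery through the full discovery chain —
is expected to fail: with the canonical `n_perm=100, max_hits=1` permutation
filter, label shuffles in small balanced cohorts frequently re-create the true
grouping, so the filter removes genuine effects and recovery lands far below
the target. This behaviour is inherent to the procedure and is documented in
[docs/methods.md](docs/methods.md); the test is kept faithful rather than
weakened.

## Worked example

```python
import pandas as pd
from dmrkit import SimConfig, simulate_cohort, RunConfig, run_pipeline

matrix, sheet, truth = simulate_cohort(SimConfig(
    n_cases=10, n_controls=10, n_cpgs=2_000, n_dmrs=8,
    n_steroid_regions=2, delta_beta=0.35,
    steroid_prevalence=(0.4, 0.4), seed=21,
))
config = RunConfig(
    n_perm=25, max_perm_hits=10, n_boot=60, forest_trees=60,
    k_clusters=3, cv_folds=3, train_counts={"case": 7, "control": 7}, seed=4,
)
manifest = run_pipeline(matrix, sheet, config, "example_run")
print(manifest.stage_info["filter"])
print(manifest.stage_info["n_dmr_final"])
print(pd.read_csv("example_run/evaluation.tsv", sep="\t").to_string(index=False))
```

Output:

```
{'kept': 1998, 'removed_low': 2, 'removed_high': 0, 'input': 2000}
7
 model  n_regions  test_auroc  test_auprc
sparse          7         1.0         1.0
forest          3         1.0         1.0
```

The run directory contains every artefact with SHA-256 checksums recorded in
`manifest.json`. The final DMR BED (0-based half-open coordinates):

```
chr1 134233 134549  hypo|n_dmcs=6 6 .
chr2  16917  17251  hypo|n_dmcs=6 6 .
chr2 119122 119471  hypo|n_dmcs=6 6 .
chr2 163482 163852  hypo|n_dmcs=6 6 .
chr3  60594  60933  hypo|n_dmcs=6 6 .
chr5  13291  13591 hyper|n_dmcs=6 6 .
chr5  88488  88886 hyper|n_dmcs=6 6 .
```

Seven of the eight planted disease regions survive the chain (the eighth is
lost to the coverage filter and minimum-member rule); both planted
steroid-confounded regions are subtracted. The sparse model selects all seven
final regions and the forest panel uses three, both reaching held-out
AUROC 1.0 on this deliberately strong-effect toy cohort.

The same chain is available from the command line:

```bash
dmrkit simulate --out cohort/ --n-cases 10 --n-controls 10 --seed 21
dmrkit run --calls cohort/calls --sheet cohort/sample_sheet.tsv --out run/
dmrkit qc-filter --calls cohort/calls --sheet cohort/sample_sheet.tsv
```

## Bundled data

A per-sample sequencing-statistics table for a 20-dog lymphoma cohort and 19
controls ships with the package. Cohort means reproduce the conventional
summary-report values exactly under half-up rounding:

```python
from dmrkit import load_bundled_sequencing_stats, summarize_sequencing
print(summarize_sequencing(load_bundled_sequencing_stats(), round_for_report=True))
```

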