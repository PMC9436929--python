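# tcellclock

Single-cell analysis of CD8+ T-cell aging: per-gene mixed-effect detection
of age-associated expression changes, classification of *how* each gene
changes (more expressing cells vs. higher expression per cell), a
mixed-effect machine-learning "cell age" clock, subpopulation-composition
trends, and UMI-consensus somatic mutation burden — together with a
synthetic-data module that plants recoverable ground truth for every stage.

The package is aimed at computational immunologists and single-cell
analysts who want a tested, reusable implementation of these methods, and
at methodologists who want planted-truth simulations to probe their
behavior.

## The models

**Age-associated genes (MELR).** For each gene, log2-normalized expression
is modeled with a random-intercept linear mixed model

```
expression ~ Age + Sex + (1 | group)
```

where all cross-sectional (single-visit) donors share one group and each
longitudinal donor is its own group, so repeat visits inform the age slope
without being confounded by donor-level offsets.  The fit is restricted
maximum likelihood; with one group it reduces exactly to OLS.  The age
slope *CO* is tested two-sided against a t distribution with n − 2 degrees
of freedom; genes with |CO| > 0.0019 (log2-normalized units per year) and
Benjamini–Hochberg FDR < 5% are called significant.

**Modes of change.** Each significant gene is summarized per donor-visit by
(i) the fraction of cells with a nonzero raw UMI count and (ii) the mean
log2-normalized expression among those positive cells.  Both measures are
regressed on age with the same mixed model; a gene whose projected change
over the cohort age span exceeds 5% in one measure is labeled
`percentage` or `expression`, in both `both`, and otherwise
`unclassified`.

**Cell-age clock (MEEN / MERF).** A cell's donor age is modeled as
`age = f(x) + b_g + ε` with `f` an elastic net (MEEN) or random forest
(MERF) over the cell's expression vector plus a one-hot sex covariate, and
`b_g ~ N(0, σ_b²)` a per-group random intercept.  Fitting alternates
between refitting `f` on the intercept-adjusted response and BLUP/variance
updates (an EM-style scheme for mixed-effect machine learning).  The
elastic-net penalty is tuned by random 10-fold cell-level cross-validation
over a 100-point log-spaced λ path; feature relevance comes from
permutation importance; group contrasts (e.g. before/after an
intervention) subtract the elapsed chronological time and report a Welch
t-test.

**Mutation burden.** Per-cell somatic variant candidates pass three
filters — TLOD > 5.3 with exome depth > 10 (SNPs only), a UMI-consensus
rule (≥ 3 alt reads forming > 50% of a UMI's reads), and a two-allele cap
per position — then per-cell counts are adjusted for cell UMI total, cell
coverage and donor exome coverage with a log-link negative-binomial
regression.  The adjustment residual on the log2(count+1) scale is
rescaled to [0, max raw count] and regressed on predicted cell age per
subset.

## Worked example

Run the whole pipeline on a small synthetic cohort (12 donors, 80 cells
per visit):

```python
from tcellclock.config import default_config
from tcellclock.pipeline import run_pipeline

cfg = default_config(
    seed=1, out_dir="demo_run",
    simulate={"n_cross": 8, "n_long": 4, "cells_per_visit": 80,
              "n_background_genes": 100},
    clock={"n_folds": 5, "n_lambda": 50},
)
report = run_pipeline(cfg)["report"]["stages"]
```

With seed 1 this prints (abridged):

```
qc:        kept_cells 1200 of 1280
trends:    Na -0.51 pp/year (planted -0.5), SCM/CM/EM rising
agegenes:  53 of 210 genes significant (24 up, 29 down)
modes:     21 percentage, 20 expression, 12 both, 0 unclassified
clock:     cv_pearson_r 0.80, rmse 9.2 y, naive younger in 12/12 donors
mutations: burden~predicted-age slope positive in all 4 subsets,
           max p = 1.7e-08 (NB adjustment, 5545/8702 records survive)
```

Reading the numbers: QC removed the planted high-mito contaminant tail;
the naive-subset composition slope recovers the planted decline of 0.5
percentage points per year; the significant gene set is dominated by the
planted age genes; the clock's cross-validated predictions track donor age
and rank naive cells younger than memory cells in every donor; and the
adjusted mutation burden rises with predicted cell age in every subset, as
planted.

Each stage is also available directly (`tcellclock.fit_melr`,
`detect_age_genes`, `classify_modes`, `fit_mixed_ml`,
`cross_validate_clock`, `filter_pipeline`, `count_and_adjust`, …) and via
the `tcellclock` CLI (`simulate`, `qc`, `proportions`, `mutations`,
`run`).

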