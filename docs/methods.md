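# Methods

This note documents the models implemented in `tcellclock`, the design of
the synthetic-data generators, the defaults and numerical choices, and
what the test suite does and does not establish.

## 1. Study design being modeled

The package targets a two-cohort single-cell design for human CD8+ T-cell
aging: a cross-sectional cohort spanning newborn to ~90 years with one
blood draw per donor, and a longitudinal cohort whose donors return after
roughly nine years (2–3 visits).  The random-effect grouping reflects
that design throughout: every cross-sectional cell belongs to one shared
group (`XS`), and each longitudinal donor forms its own group, so
donor-level offsets in longitudinal data are absorbed by random
intercepts while the cross-sectional contrast drives the age trend.

## 2. Cell quality control and normalization

Cells are retained when their UMI total lies in the inclusive window
[`umi_min`, `umi_max`] (defaults 500 and 2500 — below is shallow/broken,
above is doublet-suspect) and their mitochondrial fraction is at most
`mito_max` (default 0.20; strictly greater is removed).  The bounds are
inclusive because the exclusion rules are phrased as "above"/"below";
boundary cells are kept.

Normalization is `log2(1 + count / total_umi * scale)` per cell with
`scale` = 10,000 and a pseudo-count of 1.  Only the log2 base is inherent
to the method; the scale constant and pseudo-count are conventions and
are surfaced in the configuration because downstream effect-size
thresholds are sensitive to them.  The transform is monotone within a
cell and exactly invertible given `total_umi`.

Cross-dataset integration / batch correction is deliberately **not**
implemented: the synthetic data are generated batch-free, so nothing in
this package exercises or validates integration behavior.

## 3. Per-gene mixed-effect age regression (MELR)

Model: `y = β0 + β_age·Age + β_sex·Sex + b_g + ε`, with
`b_g ~ N(0, σ_b²)`, `ε ~ N(0, σ_e²)`, `Sex` coded 1 = male, 0 = female.

The engine profiles the REML criterion over the variance ratio
θ = σ_b²/σ_e².  For fixed θ the within-group covariance is compound
symmetric, so `(I + θJ)⁻¹` has closed form and all weighted cross
products reduce to per-group sums; the restricted likelihood is then a
1-D function of θ, minimized with bounded scalar optimization
(`xatol = 1e-8` on log θ over ±14).  The θ = 0 boundary is always checked
explicitly; boundary fits are flagged `singular` and coincide with OLS.
This makes the per-gene scan fast (thousands of genes × thousands of
cells in seconds) and makes the single-group ⇒ OLS contract exact rather
than approximate.  The solver is validated in the test suite against
`statsmodels` OLS (single group, 1e-6) and `MixedLM` (multi-group).

Inference: the age-slope p-value is a two-sided t test on n − 2 degrees
of freedom, where n is the number of observations — a deliberate,
conventional simplification (no Satterthwaite correction).  BLUPs are
`b_g = σ_b² n_g / (σ_e² + n_g σ_b²) · mean(residual in g)`.

Significance calling: Benjamini–Hochberg within the scanned gene set
(per subset), significant ⇔ |CO| > 0.0019 and q < 0.05.  The effect floor
0.0019 (log2-normalized units per year) is taken at face value as the
conventional threshold and exposed in config rather than derived — its
published gloss ("10% per cell across the age range") does not follow
algebraically from the constant, so no derivation is attempted.  Genes
detected in < 1% of the subset's cells are excluded from testing
(stability/speed floor, configurable).

A constant response returns slope 0 with p = NA.  Degenerate designs
(constant sex) drop the collinear column.

## 4. Modes of age-related change

Donor-visits, not cells, are the regression unit: for each gene the
fraction of subset cells with raw UMI > 0 and the mean log2-normalized
expression over those positive cells are computed per donor-visit
(donor-visits with fewer than 3 subset cells are dropped; visits of
longitudinal donors enter separately, grouped by donor).  Each measure is
fit with the MELR engine and projected over the cohort age span.

Thresholding: the percentage measure is compared to 0.05 in absolute
proportion units.  For the level measure the reference scale of "a 5%
change" is genuinely open; the default divides the projected change by
the gene's cohort-mean positive expression (mean of the donor-visit
means), i.e. a *relative* 5%, with an absolute-scale variant behind
`relative_level=False`.  Genes crossing neither threshold are
`unclassified` (excluded from mode counts in the published-style summary
but still reported).  Every input gene receives exactly one label.

## 5. Mixed-effect machine-learning clock

The fixed part `f` is either an elastic net (MEEN) or a random forest
(MERF); the random part is a per-group intercept.  The EM-style
alternation is:

1. `y* = y − b_g(cell)`;
2. refit `f` on `(X, y*)`;
3. residuals `r = y − f(X)`; BLUP update
   `b_g = σ_b² n_g/(σ_e² + n_g σ_b²)·mean(r_g)`;
4. moment updates with the BLUP posterior corrections:
   `σ_e² ← (1/n) Σ_g [‖r_g − b_g‖² + σ_e² n_g σ_b²/(σ_e² + n_g σ_b²)]`,
   `σ_b² ← (1/q) Σ_g [b_g² + σ_b² σ_e²/(σ_e² + n_g σ_b²)]`;
5. stop when the generalized log-likelihood changes by < `tol`
   (default 1e-4) or after `max_iter` (default 50) iterations.

Initialization is `b = 0`, `σ_b² = σ_e² = 1`.  After convergence the
random intercepts are mean-centered and the mean folded into a fixed
offset (identifiability with the learner's free intercept).  With a
single group the fit short-circuits to the plain learner, making the
"MEEN = elastic net" property exact.  Cells from unseen groups are
predicted with the fixed part only (b = 0), the standard BLUP convention.

**MEEN tuning.** The λ path is log-spaced over four decades descending
from λ_max = max|x_jᵀy_c| / (n·α) (centered data), with 100 points and
α = 0.5 by default.  The mixing α is not fixed by the method description
and is exposed in config; the ridge/lasso endpoints are covered by tests.
Fold assignment is random at the cell level (10 folds); because a donor's
cells then appear on both sides of a split, a `fold_mode="donor"`
hold-out is provided for leakage-free evaluation.  λ* is the argmin of
mean CV MSE.

**MERF defaults.** 500 bootstrap trees with a minimum of 100 observations
per node split (scikit-learn `min_samples_split`), seeded.  MERF models
are not serialized; MEEN models round-trip through a versioned JSON plus
a coefficient TSV.

**Permutation importance** permutes one feature at a time within the
evaluation set and reports the mean MSE increase over the baseline
(n_repeats draws, seeded).  **Group comparison** reports
`Δ = mean(b) − mean(a) − elapsed_years` with a Welch t test on the
shifted samples, so an expected chronological increase can be subtracted
when comparing the same subjects over time.

## 6. Mutation burden

Filters are applied in a fixed order — caller confidence (TLOD > 5.3,
exome depth > 10, SNPs only), UMI consensus, allele cap — and each is
idempotent.  The consensus rule is strict on both margins: at least 3 alt
reads in a UMI *and* an alt fraction strictly greater than 50% (3/4
passes; 2/2 and 3/7 fail).  The allele cap removes *all* records at a
(cell, position) carrying more than two distinct passing alternate
alleles, since a diploid locus supports at most two.  The full chain is
cross-checked in tests against a brute-force oracle that applies all
rules jointly to small random tables.

Adjustment: raw per-cell counts are regressed on the log covariates
(cell UMI total, cell coverage, donor exome coverage) with a
maximum-likelihood negative binomial (NB2, global dispersion; Poisson
fallback on fit failure, constant fallback on zero-variance counts).  The
description "log2 transformed, then a negative binomial model" is
ambiguous; an NB model *of* log-transformed data is not a coherent count
model, so the NB is fit on the raw counts with a log link and the
adjustment is computed as `log2(raw+1) − log2(fitted+1)`, then min-max
rescaled to [0, max raw count] (ties at the max map to the max).
Covariates enter on the log scale because depth effects are
multiplicative.  The burden-vs-predicted-age readout reuses the MELR
engine per subset: `adjusted ~ predicted_age + sex + (1|group)`.

## 7. Synthetic data

The generators emulate, per cell and gene:

- **Cohorts** — `n_cross` single-visit donors with uniform ages over the
  range, `n_long` donors with first visits in [30, 69] and gaps of mean 9
  (sd 1, floor 1) years; sexes alternate to parity; all streams derive
  from one `SeedSequence`, with one spawned sub-stream per donor so that
  removing donors leaves the others' cells bit-identical.
- **Subset composition** — per-visit proportions linear in age, clamped
  to [0, 1] and renormalized; defaults: naive 50% at birth declining 0.5
  pp/year, SCM/CM/EM rising.  Subset draws are multinomial.
- **Latent cell age** — donor age + subset offset (naive −8 y, SCM 0,
  CM +2, EM +5) + N(0, 5 y) jitter, floored at 0.  Gene effects act on
  this latent age, which is what makes the clock's within-donor
  naive/memory ordering a planted, recoverable signal rather than an
  artifact.
- **Counts** — detection Bernoulli(baseline + slope·cell age, clamped),
  then a *zero-truncated* negative binomial for detected cells, so the
  realized detection fraction equals the planted probability exactly and
  percentage-mode effects are cleanly separated from level effects.
  Negative NB means are clamped to 0.01 and counted in
  `uns["clamp_log"]`; default effect sizes keep clamping at zero or
  negligible.
- **QC structure** — mitochondrial fractions are Beta(2, 30) with a 5%
  Beta(8, 12) contaminant tail, so the 20% rule removes a nonzero
  fraction; background genes carry enough UMI that totals land inside
  the [500, 2500] window.
- **Variant evidence** — true mutations are Poisson with a log-linear
  rate `rate0 · exp(Σ β·centered log covariate + β_age·cell age)`
  (`rate0 = 0` ⇒ no mutations); their UMIs carry ≥3 reads at ~97% alt
  fraction, with configurable fractions planted to fail the TLOD and
  depth gates.  Error artifacts carry either <3 reads or a ~30% alt
  fraction, so the consensus rule removes them deterministically.
- **Calibration harnesses** — `generate_planted_lognorm` draws the
  log2-normalized layer directly from an exact linear age model (for
  regression calibration where the planted CO must be known in model
  units), and `level_slope_for_relative_span` inverts the
  count→log2-normalized mapping so mode-classification effects can be
  planted at a chosen span on the measured scale.

Two named study conditions are frozen in code: the default demo panel
(8/8/4 planted mode genes + nulls + background, ~24 donors) and
`clock_study` (20 donors, 200 cells per visit, 50 age-informative genes —
level slopes +0.022/−0.009 per year, detection spans of 0.6 — plus nulls
and background).  The clock effect sizes were chosen once, during design,
to give a clearly recoverable signal at this cohort size; no published
effect-size distributions exist to emulate, so these defaults are
testability choices, not data mimicry.

**What the synthetic data does not emulate:** batch effects and
integration artifacts, doublets, ambient RNA, gene–gene correlation
structure, nonlinear age trajectories, realistic site-frequency spectra
for mutations, or read-level sequencing error.  Passing the planted-truth
suite therefore shows the estimators are correct *under the model's
assumptions*; it does not certify performance on real data.

## 8. Problem sizes and runtime

The test suite and the acceptance script use desk-scale problem sizes
chosen as the smallest designs at which the planted effects are reliably
recoverable: ~100–200 regression instances for solver checks, 3,000 cells
for FDR calibration, 40 donors for mode recovery, 20 donors × 200 cells
for the clock, 2,000 cells for burden adjustment, and 1,000 random tables
for the filter oracle.  The full suite runs in well under a minute of
compute per stage on a single CPU.

## 9. Known limitations

- The n − 2 t test ignores the effective loss of degrees of freedom to
  the random intercept; with few groups p-values are mildly optimistic.
- Cell-level CV folds leak donor identity into training; the donor
  hold-out mode is the honest generalization estimate and is pessimistic
  relative to the cell-level numbers.
- The NB adjustment assumes a global dispersion; per-donor dispersion is
  not modeled.
- `position_allele_cap` operates per cell; recurrent artifacts shared
  across cells at one position are not pooled.
- MERF serialization is not supported; refit from the manifest instead.
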