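# Methods

## Partition coefficients

A replicate measurement carries the amount of solute extracted into the
fiber membrane, `n0` (µg), the starting concentration `C0` (µg/mL), the
formulation volume `Vd` (mL) and the membrane volume `Vm` (mL).  The
partition coefficient is the ratio of equilibrium concentrations,

    K = (n0/Vm) / (C0 − n0/Vd) = n0·Vd / (Vm·(C0·Vd − n0)),

valid on 0 ≤ n0 < C0·Vd; anything outside that domain (over-extraction,
nonpositive volumes) is rejected as a domain error rather than
propagated as a negative or infinite K.  `n0 = 0` gives K = 0 with an
*absent* log10 K rather than −∞; such rows carry no usable response and
are excluded from fitting with a warning.  Units are fixed (µg, mL,
µg/mL) because the formula is unit-consistent under exactly one
convention; no unit inference is attempted.  `Vm` is a required input —
it depends on fiber geometry and no default is defensible.

If extraction removes a fixed proportion `p` of the solute regardless
of `C0` (`n0 = p·C0`), K collapses to `p·Vd/(Vm·(Vd − p))`,
independent of `C0`.  That closed form is the *partition theory*; the
algebraic identity between the two routes is property-tested over
random draws, and the statistical content of the theory is tested on
data as described below.

## The three LFER variants

All variants regress y = log10 K on the Abraham descriptors
(E, S, A, B, V) by ordinary least squares.

* **single** — one block: intercept + 5 slopes (6 columns).
* **crossed** — an independent block per (MWF i, MWF concentration j,
  solute concentration k) treatment cell.  Dummy products F·C·W select
  exactly one block per observation; with all 90 cells populated the
  design has 540 columns.
* **nested** — solute concentration is treated as a numeric regressor
  nested within (i, j): each of the ≤ 15 blocks has intercept, 5
  descriptor slopes, and a slope β6_ij on t = log10(solute
  concentration, ppm).  Base-10 logs are used throughout; t is always
  recomputed from the stored concentration, never read from a file.

Cell-means coding is deliberate: no reference level, no shared
intercept, so each coefficient is the cell's own partial slope and the
blocks are row-disjoint.  Consequently X'X is block-diagonal and the
joint fit coincides with independent per-cell regressions — exploited
as an oracle test, not assumed by the implementation (the fit is a
genuine joint solve).

### Numerical core

Fitting uses a pivoted (rank-revealing) QR with relative tolerance
1e-10 on the R diagonal.  Collinear columns — typically a descriptor
constant within a cell, e.g. A = 0 for every solute present — are
dropped and reported by name, never silently imputed.  If no residual
degree of freedom remains after dropping, an estimability error names
the problem instead of returning garbage.  Standard errors use the
fit's pooled residual variance (there is one model, hence one σ²);
confidence intervals use Student-t quantiles at the residual df.  The
separate per-cell fits of the single LFER (one regression per
treatment cell, each with its own residual variance, skipping cells
with fewer than 7 rows) are provided alongside, so both
pooled-variance and per-cell-variance standard errors exist and are
labelled by construction.

r² is computed about the grand mean of the response for every variant,
making it comparable across models even though the cell-means designs
contain no global intercept.

### Prediction

Predictions map new rows onto the fitted columns by (descriptor, cell)
metadata.  A prediction is flagged absent (NaN, counted and reported)
when the row's cell has no block in the fit or the row loads on a
dropped column — in both cases the needed coefficient is inestimable
from the training data.  This is deliberately conservative: a column
dropped for exact collinearity could in principle still support
prediction inside the training column space, but flagging keeps the
rule simple and honest.

## Cross-validation

Q²_LOO = 1 − Σ(y_l − ŷ_{l,−l})² / Σ(y_l − ȳ)², with ȳ the mean over
all *used* responses of the full dataset (not fold-specific means).
The fold predictions use the exact hat-matrix identity
ŷ_{l,−l} = y_l − e_l/(1 − h_l); a brute-force refit path exists and the
two agree to 1e-8 (tested).  Folds with leverage ≈ 1 are unpredictable
and excluded from numerator and denominator, with the count reported.

Q²_LOSO removes *all* rows of one solute per fold — every replicate,
every cell — and refits genuinely (no group-deletion shortcut is
correct in general).  With replicates present, LOO trains with
near-full knowledge of the held-out solute and overstates predictive
power; LOSO measures prediction of chemically new solutes.  Duplicating
every row leaves Q²_LOSO exactly unchanged (duplicated training folds
give identical least-squares fits, and numerator and denominator scale
together) while Q²_LOO rises toward r² — this is the motivating
property and is asserted in the tests.  A solute whose removal makes a
needed column inestimable (e.g. the only A > 0 solute) has its rows
excluded and counted; the exclusion rule is a documented package
choice, since no convention is canonical.

## Partition-theory tests

Under the nested model the partition theory is exactly
H0: β6_ij = 0 for all i, j.

* **Global:** extra-sum-of-squares F test of the nested design against
  the same design with every t column removed.  The numerator df is
  the number of t columns actually estimable; if none is (a single
  concentration level), the test is degenerate and says so.
* **Per cell:** t tests of each β6_ij from the pooled single-model fit
  (not per-cell refits — the hypothesis is stated on one model; the
  choice is recorded in the report metadata).  Significance is called
  at α/15: the Bonferroni divisor stays at the design's 15 cells by
  default even when fewer are estimable, with a `tested` option to
  divide by the number actually tested.
* **Subsets:** both tests repeated on concentration subsets (default:
  all six; the five lowest; four lowest; three lowest; {0.05, 0.1,
  0.5}; {0.01, 0.05}; {0.05, 0.1}), each requiring ≥ 2 distinct
  levels.  The design is rebuilt from scratch per subset.  Output is
  one row per subset: global p, supporting cells (with n), violating
  cells (with n).

## Synthetic-data generator

The generator exists because the raw measurements behind this kind of
study are typically unavailable; it makes every stage testable and
supports calibration/power studies.  Defaults emulate the study
conditions:

| parameter   | default | meaning |
|-------------|---------|---------|
| solutes     | all 37  | packaged descriptor table |
| cells       | 5 × 3 × 6 = 90 | MWF × MWF % × solute ppm grid |
| replicates  | 3       | per (solute, cell) |
| dropout     | 0.535   | P(replicate missing), i.e. 46.5 % retention ≈ 4645 of 9990 rows |
| noise_sd    | 0.25    | Gaussian σ on log10 K |
| model       | nested  | generating equation |

Responses follow the nested model:
log K = β0_ij + β1_ij·E + … + β5_ij·V + β6_ij·t + ε, ε ~ N(0, σ²).
The default coefficient table is fixed and versioned with the sign
structure the analysis is designed to detect: V slopes positive, A and
B slopes negative, the E slope changing sign across mineral-oil
concentrations, and β6 negative everywhere except exactly three null
cells (MO/0.05, PEG/5, SYN/0.05).  Magnitudes were chosen once so that
generated log K spans roughly −1.5 to 3 with a mean near 1.3 —
realistic for this assay — and were not revisited.  noise_sd = 0.25 is
a calibration knob giving within-cell scatter small relative to
between-solute spread, not an estimate of any study's residual sd.

Dropout is independent Bernoulli per replicate (missing completely at
random).  Real missingness — detection limits, calibration-range
exclusions — is *not* random and is not modelled; concentrations are
noise-free on the exact grid, and noise enters on the log scale only.
Passing tests on generated data therefore demonstrate correctness of
the estimators and tests under the assumed model, not robustness to
informative missingness or measurement artefacts in real data.  A
crossed-factors generator (per-(i,j,k) coefficient blocks) exists for
robustness studies; expanding the nested truth into crossed blocks
reproduces the nested means exactly, which is the tested baseline.

Identical (config, seed) pairs give byte-identical CSV output; a
missing seed is an error, never silent nondeterminism.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the pipeline at the full
study geometry (37 × 90 × 3) for structural, power and oracle checks;
calibration studies use 200 generate→fit cycles for CI coverage, 500
null draws for the global test's type-I error in the suite (200 in the
acceptance script), and 5 seeds for the LOSO model-ordering comparison.
These sizes are the package's choices balancing Monte-Carlo resolution
against run time.

## Known limitations

* Per-coefficient empirical CI coverage over a few hundred replications
  has binomial noise of ±1.5 percentage points; judging 105
  coefficients simultaneously against a tight band will flag a few
  coefficients by chance even under perfect calibration.  The pooled
  coverage rate is the stable calibration summary.
* The LOO hat identity assumes the fold keeps the full fit's retained
  column set; folds that would change the rank are flagged
  unpredictable rather than silently refit.
* No regularised or robust regression, no descriptor selection, no
  k-fold or bootstrap validation, and no modelling of extraction
  kinetics — the package covers equilibrium partitioning and the three
  LFER variants only.
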