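# Methods

## The quantification problem

Paracetamol, acetylsalicylic acid, caffeine, naproxen and ibuprofen all
absorb between 220 and 240 nm with broad, featureless UV bands. In a
mixture no wavelength is selective for any one drug, so univariate
calibration fails. The package treats the problem as constrained bilinear
factorization: a samples × wavelengths absorbance matrix **D** is
decomposed as **D = C Sᵀ + E**, and the concentration factor **C** is tied
to reference standards so that, at convergence, its columns are in µg/mL.

Bilinear factorizations are not unique — any invertible transform **T**
gives an equally good fit via (CT)(T⁻¹Sᵀ). The package stacks three
mechanisms against this rotational/intensity ambiguity:

* nonnegativity of both factors,
* unit-length normalization of each spectral profile at the end of every
  sweep (the concentration scale is then owned entirely by the correlation
  constraint),
* the correlation constraint itself, which anchors the calibration rows of
  each quantified component to their reference values every sweep.

## ALS iteration

Each sweep performs, in order:

1. solve **C** from **D** and the current spectra by nonnegative least
   squares (per-sample active-set NNLS via `scipy.optimize.nnls`);
2. apply the correlation constraint to every component matched to an
   analyte (see below);
3. solve **Sᵀ** from **D** and the constrained **C**, again by NNLS;
4. evaluate LOF% = 100·√(ΣE²/ΣD²) and stop when its relative change is
   below `tol_pct` (default 0.1%, cap 50 sweeps); otherwise normalize the
   spectral rows to unit length and continue.

The reported iteration count includes the sweep that triggers convergence.
Two numerical guards: an absolute LOF floor of 1e-10% counts as converged
(at machine-zero residuals the relative test only sees round-off), and a
run that hits the cap returns `converged=False` with a warning rather than
raising.

### Correlation constraint

For each quantified component, the resolved concentration values *x* of
the calibration samples are regressed against their reference values *y*
(*x* = *m·y* + *n*). The whole column — calibration and unknown rows
alike — is converted to concentration units through the inverted line,
*c* = (*x* − *n*)/*m*, and the calibration rows are then re-anchored
exactly on their references. The re-anchoring matters: mapping the column
through the line alone is an affine transform that preserves whatever
mixed pattern the column currently carries, so the rotational ambiguity
survives and the algorithm can converge to a noise-level spectral fit
with useless quantitation. Injecting the reference pattern each sweep is
what forces the decomposition toward the rotation in which components
coincide with analytes. The reported per-analyte slope/intercept
(b₁ = 1/*m*, b₀ = −*n*/*m*) describe the resolved→concentration mapping.

Components are matched to analytes once, at the first sweep, by a
one-to-one Hungarian assignment maximizing the correlation between
resolved columns and reference columns over the calibration rows. With
fewer components than analytes the worst-fitting analytes stay unmatched;
their predictions fall back to a single-component regression, whose large
cross-validation error is precisely how underfitting shows up in the rank
scan.

### Prediction read-out

Quantitative predictions (including for calibration samples) are computed
after convergence: concentrations are resolved once more against the
converged spectra and mapped through the final calibration lines *without*
re-anchoring, so calibration predictions display genuine model error
(`MCRResult.C_predicted`). Predicting external unknowns appends their
spectra to the calibration matrix as unknown rows and re-runs the ALS
seeded with the fitted model's resolved spectra — it is the developed
calibration model that predicts, and the warm start converges in 2–4
sweeps. SIMPLISMA seeds every calibration fit.

## SIMPLISMA initialization

Purity of variable *j*: *p*ⱼ = σⱼ/(μⱼ+α), with offset α =
`offset_pct`/100 · max(μ) (default 1%) damping noise-dominated weak
variables. The first selection maximizes raw purity; each later round
multiplies purity by the determinant of the correlation-around-origin
submatrix of the candidate plus the already-selected variables, which
suppresses near-duplicates — important on a 26-point grid where
neighbouring channels are nearly collinear. Default direction is
`"spectral"` (scan wavelength columns; the profiles are D-columns, a
concentration-like seed); `"concentration"` transposes the scan. Selection
is invariant to row permutation and positive scaling of D.

## Rank selection

Leave-one-out cross-validation: for each candidate rank, every calibration
sample is held out in turn, the model refitted on the rest and the held-out
spectrum predicted as an unknown; RMSECV is accumulated per analyte. The
chosen rank is the smallest whose mean RMSECV lies within
`improvement_threshold` (default 5%, relative) of the curve minimum. The
comparison is anchored at the minimum rather than at the next candidate
because badly underfitted ranks produce a non-monotone error head (two
hopeless models can rank in either order), which would trip a
successive-pair rule prematurely. A Haaland–Thomas style F-test between
successive RMSECVs is the classical alternative; with 25 calibration
samples it is noisy, and the fixed band is transparent and testable.

## Synthetic data

The generator emulates the study conditions end-to-end:

* **Grid** — 220–240 nm at 0.8 nm (26 points).
* **Designs** — the published 25-mixture five-factor five-level calibration
  design and 15-mixture validation design, embedded verbatim (including two
  printed anomalies, kept as-is: calibration mixture 8 PAR = 3.5 µg/mL
  where the five-level scheme elsewhere uses 3.8, and validation mixture 1
  ASA = 0.5 µg/mL, below the stated 1–15 range).
* **Pure spectra** — five frozen Gaussian-band profiles: a shared curved
  envelope at 229.5 nm (σ = 4.1 nm) carrying the severe overlap (all
  pairwise Pearson correlations ≥ 0.5, minimum 0.52) plus one narrow
  analyte-specific band each. The 5×26 matrix has full rank and condition
  number ≈ 21, so the system is identifiable yet nowhere selective. NPX
  and IPF have the lowest mean absorptivities, mirroring their poor
  absorption in this window. Band heights were fixed once, by first-order
  noise propagation through (S Sᵀ)⁻¹, so that per-analyte resolution noise
  under the default noise model supports r² ≥ 0.999 — i.e. the synthetic
  system is as quantifiable as the real one evidently was.
* **Noise** — one Gaussian draw per point with variance
  additive² + (proportional·signal)²; defaults 0.0005 AU and 0.2%,
  a quiet double-beam instrument. Noise may push an absorbance slightly
  negative; values are left as-is (clipping would bias the noise model).
  Same seed → bit-identical matrices.

What the generator does **not** emulate: baseline drift, wavelength
mis-registration, stray light, excipient interference, inter-day
instrument variation, and the real (unpublished) band shapes of the five
drugs. Passing tests therefore demonstrate that the algorithmic pipeline
recovers known ground truth under realistic noise and severe overlap; they
do not certify performance on any particular real instrument or
formulation.

## Figures of merit and statistics

For n samples with references cᵢ and predictions ĉᵢ:
RMSEP = √(Σ(cᵢ−ĉᵢ)²/n); bias = Σ(cᵢ−ĉᵢ)/n;
SEP = √(Σ(cᵢ−ĉᵢ−bias)²/(n−1)); RE% = 100·√(Σ(cᵢ−ĉᵢ)²/Σcᵢ²);
slope, intercept and r² from the least-squares line of predicted on
actual. The identity RMSEP² = bias² + SEP²·(n−1)/n holds algebraically and
is property-tested. Standard-addition recovery is 100·(X−Y)/Z (found after
spiking, found before, amount added), evaluated at 80/100/120% of the test
concentration. Precision is the sample-SD RSD% per replicate group; the
intraday/interday distinction lives in the grouping the caller supplies.
Method comparison uses the paired t statistic with a two-tailed critical
value at α and the plain variance ratio F = var₁/var₂ against the
upper-tail F quantile at α with (n₁−1, n₂−1) degrees of freedom — the
ratio is deliberately not reordered larger-over-smaller, matching the
tabulation convention of analytical method-comparison tables (values
below 1 occur).

## Problem sizes and determinism

The full synthetic study (both designs, a 5-component fit, 25 LOO folds
with one augmented prediction each, plus the external validation
prediction) completes in a few seconds on one core; matrices never exceed
40×26. Every stochastic step flows from a single integer seed: the
calibration set uses the seed itself, the validation set seed+1, and all
fits are deterministic given their inputs.

## Known limitations

* The correlation constraint assumes a linear resolved↔reference
  relationship per analyte; strongly nonlinear detector response would
  need a different local model.
* Component–analyte matching is fixed at the first sweep; pathological
  seeds that swap identity mid-run would keep the initial assignment
  (not observed under the shipped generator).
* Closure, unimodality, equality and trilinearity constraints, and
  multi-set (augmented-matrix) MCR, are out of scope.
* Automatic wavelength-window optimization is not provided; the 220–240 nm
  window is the package default by design.
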