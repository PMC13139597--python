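# Methods

`heatmir` implements a complete desk-scale analogue of a milk FT-MIR
pipeline for phenotyping the individual heat-stress response of dairy cows:
from weather and routine milk-recording data, through a random-regression
test-day model, to two spectral calibrations, their combination, and a
population-level mixed model.  Because no public reference dataset exists
for this problem, the package ships a first-class synthetic-data generator
whose planted effects define what every downstream stage must recover.

## Heat-load definition (THI)

Hourly dry-bulb temperature T (°C) and relative humidity RH (%) are combined
into the temperature-humidity index

    THI = (1.8·T + 32) − (0.55 − 0.0055·RH)·(1.8·T − 26)

THI is strictly increasing in T (∂THI/∂T = 1.8·(0.45 + 0.0055·RH) > 0) and
increasing in RH exactly above T = 130/9 ≈ 14.44 °C.  Daily THI is the mean
of the 24 hourly values (strict completeness by default; a lenient mode
accepts ≥ 20 h and is the only missing-data concession).  The test-day heat
exposure `thi_td3d` is the mean daily THI of the test day and the three
preceding days, rounded half-away-from-zero to an integer — the tie policy
is a package choice (the convention is not standardized) and is configurable.

## Test-day residual model

For each trait (24 h milk yield, fat %, protein %, Mg concentration) a
single-trait random-regression model is fitted to the historical records:

    y = Xb + Q(Z₁a + Z₂p) + e

with fixed effects herd×calendar-year, month of recording (12 levels,
month-of-year), lactation-number class (1, 2, 3+) and a 19-class DIM
binning; the printed bin sequence leaves DIM 305 in two bins, resolved here
as 251–304 / 305–365.  Each animal carries three additive-genetic and three
permanent-environment regression coefficients on Legendre polynomials
P0 = 1, P1 = x, P2 = (3x² − 1)/2 of x = 2(DIM − 5)/360 − 1 (capped at 1
above DIM 365).  Genetic coefficients have covariance A ⊗ G_a, where A is
the pedigree numerator relationship matrix whose sparse inverse is built
directly by Henderson's rules (inbreeding ignored — the simple-rule regime);
permanent-environment coefficients have covariance I ⊗ G_p.

No variance components are estimated (REML is out of scope); defaults are
G_a = G_p = diag(0.2, 0.02, 0.01)·var(y) and σ²_e = 0.5·var(y), giving
moderate shrinkage, and are user-replaceable.  Identifiability uses
reference-level constraints: the herd-year factor keeps all levels, every
subsequent factor drops its first level.  The mixed-model equations are
solved densely (LAPACK) up to 2,000 equations and by sparse LU
factorization above; a direct factorization was preferred over an iterative
scheme because it is exact, deterministic and fast at the problem sizes this
package targets.  A singular system (confounded fixed levels) raises an
error rather than returning a pseudo-solution.

Residuals e are divided by their population (n-denominator) standard
deviation over the fitted dataset; at the intended record counts the n vs
n−1 distinction is negligible, but the convention is fixed and tested.

## Reference heat-stress classes

Udder surface temperatures (PM and AM milking, averaged into one record per
cow-visit) are referenced against the same farm's thermoneutral-visit
distribution, summarised by its mean and *sample* (n−1) SD.  A heat-wave
record is

* X1 (affected):     mean temp > mean + 3·SD  AND  standardized protein and
  Mg residuals both < −0.1;
* X0 (non-affected): mean temp < mean + 2·SD  AND  both residuals ≥ −0.1;
* X0.5 otherwise — including, structurally, every temperature between the
  2 SD and 3 SD bounds.

All inequalities are strict/inclusive exactly as written; equality with a
threshold falls into X0.5.  The class-model training set takes every X1
record, the rule-based X0 records topped up to |X1| with records drawn
(seeded, without replacement, globally across farms) from a control pool of
non-summer (no June–August) records with `thi_td3d` < 60, and a seeded
sample of |X1| intermediates.

## Spectral calibration

Spectra are 1,060-point standardized absorbance vectors.  Preprocessing:
gap-5 first derivative d(i) = A(i−2) − A(i+2) (points 3–1,058, 1,056
values; the sign convention follows the subtraction order stated above and
a global flip is immaterial to PLS/RF), then a fixed low-noise region mask
keeping points 12–170, 210–218, 223–230 and 495–530 (212 values).
Wavenumber labels are derived from a linear axis anchored at point 12 =
968.09 cm⁻¹ and point 170 = 1,577.49 cm⁻¹; point numbers remain the
authoritative coordinates.

**Temperature model.**  PLS regression (mean-centered, unit-variance
scaled) of the mean udder temperature on the masked derivative values.
Cross-validation is 5-fold, grouped on (cow, thermal period) so a
cow-period never appears in both calibration and validation — the same cow
*may* appear in both folds under different periods, which is deliberate:
the contrast of interest is condition-dependent, not cow-specific.  A
leakage assertion runs on every fit.  Inside each fold, variables are
pre-selected on the calibration portion only, keeping points with
|Pearson r| ≥ 0.3 against temperature (absolute value: heat-stress bands
can deflect in either direction).  R²cv is computed from pooled out-of-fold
predictions against the global mean, RMSEcv = √(SSE/n); the component count
(1–50) is chosen by the highest R²cv unless pinned.  The final model refits
on all data; its JSON artifact stores the selected points, coefficients,
intercept and training column means, so prediction uses exactly the stored
columns with no re-selection.

**Class model.**  Two-stage random forest (500 trees, Gini, minimum node
size 1, mtry = ⌊√p⌋ — the ⌊√p⌋ rule rather than a hard-coded value, since
the published 26 simply reflects that study's p): a first forest ranks
impurity importance, the final forest uses the top 50 variables plus a
month heat-risk dummy (April–September = 1, October–March = 0) that is
force-included.  For the out-of-fold confusion report both stages rerun
inside each fold's calibration portion, keeping the report leakage-free.
Reported metrics: global accuracy and per-class sensitivity/specificity.

**Combination.**  combined = 1 if predicted temperature ≥ 36 °C and class
X1; 0.5 if ≥ 36 °C and class X0.5; else 0.  The rule is monotone in both
arguments.

## Population analysis

Records are filtered to DIM 5–365, milk yield ≥ 3 kg, and herd-test-days
(HTD) with ≥ 10 records — the HTD count evaluated after the record-level
filters and re-checked once (one extra pass), a package choice.  The
combined phenotype is transformed into Snell-type scores via a logistic
liability: cumulative class proportions P_k define boundaries
t_k = logit(P_k), and each class scores the mean of a standard logistic
variable truncated to its interval (closed form: the antiderivative of
x·f(x) is x·F(x) − log(1 + eˣ)).  Scores are strictly increasing and
invariant to rescaling the frequencies.  Published scores produced by other
Snell variants are not reproducible from this construction and are not
treated as ground truth.

The mixed model  y = HTD + lact_class + DIM_class(5 d, DIM 365 merged into
class 73) + milk_class(7 bins: < 15, [15, 20), …, ≥ 40 kg) + animal + pe + e
reuses the MME solver with scalar animal (A-structured when a pedigree is
supplied) and permanent-environment effects; variance ratios default to
0.05 : 0.05 : 0.90 of the score variance.  THI summaries average the
combined value per integer `thi_td3d` class, suppressing classes under a
minimum count (1,000 for population scale; configurable — desk-scale runs
use 50).

## Synthetic data: what is emulated, what is not

The generator plants every effect the analysis is meant to detect:

* **Weather**: hourly seasonal + diurnal sinusoids per farm with Gaussian
  noise (0.5 °C), RH anti-correlated with temperature and clipped to
  [5, 100] %; one summer heat wave per farm (triangular day-level envelope,
  default 7 days) whose bump amplitude is calibrated by root-finding so the
  recomputed peak-day daily THI hits the configured target (default 74–76).
* **Heat load** of a record:  max(0, thi_td3d − 60) · (1 − tolerance) ·
  parity multiplier (0.6 / 1.0 / 1.4 for classes 1 / 2 / 3+) · stage
  multiplier (0.6 + 0.9·exp(−½((DIM − 35)/55)²), peaking in early
  lactation).  Per-cow tolerance ~ N(0.30, 0.15²) clipped to [0, 1].  The
  parity and stage multipliers encode the well-documented higher
  susceptibility of multiparous and early-lactation cows and are what the
  population model is expected to recover; setting them to 1 recovers the
  bare effect-size formulation used in the unit tests.
* **Test-day traits**: Wilmink-type lactation curves (a + b·e^(−0.05·DIM)
  + c·DIM), parity shifts, herd-year, sire-structured genetic and
  permanent-environment effects, i.i.d. noise, and heat depressions of
  0.012 %/THI-unit-load (protein), 0.5 mg/L (Mg, simulated directly in
  mg/L around a herd mean of 100 — the unit is a labelling convention
  only, since downstream use is via standardized residuals), 0.04 kg scaled
  by yield level (milk), 0 (fat).  Protein and Mg carry the largest
  depressions relative to their residual SD, fat essentially none,
  matching the intended detection pattern.
* **Spectra**: baseline + fat/protein/Mg band signatures + a heat-stress
  signature proportional to the heat load + i.i.d. noise (0.001).  Band
  signatures use narrow Gaussian bumps (widths 6–40 points) so they
  survive the gap-5 derivative the way real MIR absorption bands do; the
  heat signature peaks at 0.003 absorbance per THI-unit load.
* **Surface temperatures**: farm baseline (~35 °C) + 0.25 °C per THI-unit
  load + 0.3 °C noise; PM uses the 17:00 hourly THI of the visit day, AM
  the cooler 06:00 THI of the next morning; the stored record is their
  mean.  Heat-wave visits fall on the wave's peak day (a monthly test
  day), thermoneutral visits on the October test day.

Not emulated: instrument-specific absorbance magnitudes and
standardization, scatter/water artefacts, somatic-cell effects, pregnancy
and culling dynamics, and real weather-station geometry (stations map 1:1
to farms).  Passing tests therefore demonstrate that the *procedure*
recovers planted structure under realistic noise, not that any particular
real-data performance level would be attained.

## Validation design

* Solver exactness: the sparse MME path is compared with an independent
  dense GLS/BLUP oracle (direct inversion of V = ZGZ' + Iσ²) on hundreds of
  random small systems, and Henderson's A-inverse against the tabular
  relationship matrix on random non-inbred pedigrees.
* Residual recovery: the expected heat-wave residual mean is *not* the raw
  planted depression over the residual SD — the month and herd-year fixed
  effects absorb part of a summer-confounded depression.  The expectation
  is therefore computed by fitting the identical model to the noise-free
  dataset of the same configuration (deterministic propagation of the
  planted effect through the fixed-effect projection); the noisy run must
  agree within 3 Monte-Carlo SE and be negative.
* Calibration recovery: a planted linear spectrum→temperature map must be
  recovered with cross-validated slope within 3 SE of 1 (and exactly, to
  1e−6 in R²cv, in the noise-free limit); separably planted classes must
  exceed 0.95 out-of-fold accuracy while label permutation drops accuracy
  to 1/3.
* Population recovery: at desk scale (a few thousand records) the 73-bin
  DIM profile is noisy at single-bin resolution, so stage-susceptibility
  recovery is assessed on a 9-bin moving average (peak inside the planted
  above-average susceptibility window) plus the early-vs-late contrast,
  alongside the strict parity ordering and the THI response curve
  (≈ 0 below THI 50, steep rise above the planted threshold).

Problem sizes used in the shipped checks — 2 farms × 100 cows × 2 years for
residual recovery, 3 farms × 30 cows × 2 years for the end-to-end run, 400
samples for the calibration checks — were chosen as the smallest designs at
which the planted effects are identifiable with comfortable margins.

## Reproducibility

One master seed drives everything; per-component generators are derived
from it through named `SeedSequence` children, so stages are independently
reproducible.  Identical configuration and seed give byte-identical CSV
artifacts (fixed column order, fixed float format).  Every pipeline run
appends stage entries (config snapshot, seeds, output SHA-256 digests) to a
JSON-lines manifest.  The class-model artifact stores the recipe (selected
columns, forest configuration, seed, training-table reference) from which
the seeded forest is rebuilt exactly at prediction time; the PLS artifact
stores its coefficients directly.

## Known limitations

* Variance components are assumed, not estimated; standardized residuals
  are only as calibrated as the supplied ratios.
* A-inverse ignores inbreeding (fine for the generator's non-inbred
  pedigrees; a flagged extension would be needed for deep real pedigrees).
* The Snell variant is one of several in use; downstream solutions are
  invariant to affine rescaling of the scores, but absolute score values
  are convention-dependent.
* The temperature model extrapolates when applied to spectra far from the
  two calibration visits (e.g. unusual composition); predictions regress
  toward the training mean there, which inflates low-THI predicted
  temperatures while leaving the combined phenotype (gated by the class
  model) near 0.
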