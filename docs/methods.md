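# Methods

This note records the statistical model behind `faniche`, the numerical
conventions it fixes, what the synthetic-data generator does and does not
emulate, and the design choices made where more than one convention
circulates in the geometric-morphometrics and spatial-ecology literature.

## Shape model and superimposition

Configurations are k landmarks in 2D. Superimposition is full generalized
Procrustes analysis: every configuration is centered, scaled to unit
centroid size, and rotated by the closed-form 2D orthogonal-Procrustes
solution onto the running consensus; the consensus is the renormalized
mean, iterated until its Procrustes movement falls below `tol = 1e-10`
(default `max_iter = 100`). Two conventions deserve mention:

* **Reflections are never allowed in any fit** (the 2D closed form
  produces proper rotations only). An improper fit would silently absorb
  the left/right asymmetry signal the package exists to measure.
* **No tangent-space projection** is applied; Procrustes coordinates are
  used directly. For within-population variation of the magnitude this
  pipeline targets (Procrustes distances ≲ 0.05) the difference between
  Procrustes and tangent coordinates is far below the test tolerances;
  users comparing against software that projects should expect
  discrepancies only in the 4th significant digit or beyond.

Dispersed shape samples (pairwise Procrustes distances approaching the
sphere's injectivity radius) converge slowly; the iteration then returns
`converged=False` with a warning rather than failing. Degenerate
(zero-centroid-size) configurations are rejected; collinear ones align
fine generically.

## Object symmetry and FA scores

The reflect-relabel operator centers a configuration, negates x, and
swaps each left/right landmark pair. It is linear (after centering) and
an involution, so the coordinate space splits into a symmetric (+1) and
an asymmetric (−1) eigenspace; after removing the non-shape directions
each has dimension d_s = d_a = 2l + m − 2.

FA scoring follows the object-symmetry procedure: one joint GPA over all
originals and all reflected copies (2n configurations); per specimen the
symmetric component is the mean of its two aligned copies, and

* `fa_score` = ‖aligned original − symmetric component‖ (Procrustes
  distance units), the literal "deviation from the symmetric consensus";
* `da_corrected_score` = ‖asymmetry vector − mean asymmetry vector‖,
  which removes directional asymmetry (DA) first.

Both are always computed, because analysis ecosystems differ in whether
the per-individual FA value is DA-corrected; the pipeline's default
response is the uncorrected score, switchable with `da_correct`.
Specimens with replicate digitizations are averaged after alignment
before scoring (one score per specimen), matching the design in which
replicates exist only to estimate error.

## Procrustes ANOVA for measurement error

With every specimen digitized r ≥ 2 times, all 2nr aligned copies enter
a balanced two-factor decomposition (individuals × sides with
replication): individual SS from specimen means of the symmetric
component, side SS from the mean asymmetry (DA), individual × side SS
from specimen-specific asymmetry (the FA line), error SS from replicate
deviations. SS are exactly additive. Degrees of freedom use the
object-symmetry subspace dimensions (individual: (n−1)d_s; side: d_a;
individual × side: (n−1)d_a; error: n(r−1)(d_s+d_a)), which makes mean
squares comparable with the values standard morphometrics software
prints. Under an additive Gaussian model the FA/error mean-square ratio
estimates (σ_e² + rσ_fa²)/σ_e² and its F-test at the stated df is well
calibrated — the suite verifies a 5% nominal rejection rate within
Monte-Carlo error. The reflected copies exactly duplicate the originals'
error, which doubles every SS but cancels in all ratios.

## Disparity and allometry

Morphological disparity is the within-population Procrustes variance,
Σᵢ d²(xᵢ, group mean)/(n−1) on the full Procrustes coordinates
(symmetric plus asymmetric variation). The divisor is exposed
(`divisor="n"` available) because both conventions exist in the
literature; (n−1) is the default as the unbiased sample variance.
Disparity on full shapes means a population with large injected FA
variance has slightly elevated disparity too; the two responses are
nevertheless separable (symmetric-only variation yields zero FA but
positive disparity, and the suite tests this).

Allometry is the multivariate OLS regression of every Procrustes
coordinate on centroid size (raw size by default, `log_size` available);
`percent_explained` = 100·SS(fitted)/SS(total), with significance from a
permutation test (default 999 permutations, +1/+1 corrected), the
standard approach for multivariate shape regressions.

## Spatial statistics

* **Extraction.** Local suitability is the value of the cell containing
  the locality under half-open cell intervals [west, east) × [south,
  north); regional suitability is the mean of the 3×3 block centered on
  the focal cell — 9 cells ↔ 9 km² at ~1 km² resolution — truncated at
  raster edges and skipping missing cells rather than padding with the
  sentinel, which would bias the mean. An `exclude_focal` option gives
  the 8-neighbor ring instead.
* **Weights.** Inverse great-circle distance (haversine, R = 6371 km),
  unstandardized by default; `row_standardize=True` reproduces the
  convention several R packages apply internally (the package's Moran
  implementation matches `ape::Moran.I` exactly when given
  row-standardized weights — verified in the suite against an R oracle).
  Euclidean distance on degrees is avoided because survey localities can
  span tens of degrees of latitude.
* **Moran's I.** I = (n/S₀)·Σwᵢⱼzᵢzⱼ/Σzᵢ², expectation −1/(n−1), with
  the closed-form variance under the normality assumption and a
  two-sided z-test; a permutation p-value (seeded) is reported alongside.
* **Layer selection.** PCA of the correlation matrix of co-registered
  environmental layers (listwise deletion of cells missing in any
  layer); the smallest set of leading axes reaching the variance
  threshold (default 0.95) is kept and the layer with the largest
  absolute loading on each kept axis is selected, deduplicated in axis
  order. When layers are mutually independent the leading eigenvalues
  are nearly degenerate and the per-axis argmax is not identifiable —
  selection is then effectively arbitrary among near-ties, which is
  inherent to the rule, not to this implementation.

## Association battery

Eight simple OLS regressions: {mean FA, disparity} × {local suitability,
regional suitability, sample size, mean centroid size}, each reported as
F(1, n−2), p, R², slope, intercept. No multiple-testing gate is applied
(the tests are treated as independent hypotheses); a Holm-adjusted
p-value column is emitted for transparency. Residual normality is logged
as a Shapiro–Wilk diagnostic, never used as a gate. Degenerate rows
(constant predictor or response, missing suitability) are skipped with a
warning and the suite continues.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the
survey-scale conditions used throughout the tests: 22 populations, 380
specimens (17–18 per population), 40 landmarks (17 bilateral pairs + 6
midline), 50 specimens digitized twice for the error test.

Per specimen, in the tangent space of a unit-centroid-size symmetric
mean shape (so all sds are directly in Procrustes units):

* individual symmetric deviation: iid N(0, σ_ind²) on an orthonormal
  basis of the symmetric subspace, σ_ind = 0.01 — within-population
  shape variation an order of magnitude above the asymmetry signal, as
  in real skull data;
* FA deviation: iid N(0, σ_fa(s)²) on an orthonormal basis of the
  asymmetry subspace, with the linear link σ_fa(s) = a − b·s (floored at
  ε > 0), s the suitability of the population's raster cell. Drawing in
  the subspace basis (not landmark-wise) makes the injected sd
  well-posed: the resulting FA score is σ_fa·χ_{d_a}, so the expected
  score is c_d·σ_fa with c_d = E[χ_d]. Defaults are stated on the
  score scale — expected mean FA 0.020 at s = 0, slope −0.004 per unit
  suitability — and converted through c_d;
* optional directional-asymmetry offset (zero by default, as DA is a
  nuisance in this design);
* per-digitization isotropic error, σ_err = 0.0026 by default, a level
  at which the FA/error mean-square ratio in the 50×2 error design is
  ≈3.5 — digitizing noise clearly smaller than the FA signal but not
  negligible, as careful manual digitization achieves.

Digitized records are scaled to a specimen centroid size ~N(30, 1.5²)
(arbitrary length units) and given a random rotation and translation, so
the raw files look like image coordinates and exercise the full
superimposition.

The suitability raster is a logistic transform of a standardized smooth
latent field (low-order trend plus squared-exponential bumps), spanning
most of [0, 1] as an SDM surface over a species' full range does.
Localities sit at cell centers (so extraction is exact) and are
stratified across the suitability gradient, as a survey covering a
species' distribution would be.

**What passing tests do and do not show.** Measurement error enters each
score as ‖a + e‖ and therefore inflates mean FA nonlinearly
(E = c_d·√(σ_fa² + σ_err²)), which *attenuates* the fitted FA–suitability
slope relative to the injected one — with the default σ_err the fitted
slope is ≈0.65–0.75 of the latent −0.004. Slope-recovery checks are
therefore run at σ_err = 0, where the injected score-scale slope is the
true regression slope; runs with the default error level demonstrate the
same qualitative association at a flatter slope. The generator draws
independent Gaussian deviations: it does not emulate landmark-specific
digitizing error, allometric shape–size coupling (sizes are independent
of shape by default), antisymmetry, or spatially structured residual
variation beyond what the suitability link induces. Passing tests
validate the estimators and their calibration under this model, not the
biology of any particular dataset.

## Problem sizes in the test suite

Simulation-backed checks use: 500 replicates of the 50×2 error design
for the ANOVA null calibration; 200 replicates of the 22-population /
380-specimen survey for slope recovery and 200 for its null; 500
replicates for the Moran null; 10,000 permutations for permutation
nulls. These sizes put the Monte-Carlo error comfortably below the
asserted tolerances while keeping the default test run around half a
minute.

## Known limitations

* 2D landmarks only; no semilandmarks, no 3D.
* The TPS dialect covers `LM=`, `IMAGE=`, `ID=`, `SCALE=`; other keys
  are skipped with a warning. Missing landmarks are not supported.
* Rasters are ESRI ASCII grids in geographic coordinates; GeoTIFF and
  projected grids are out of scope.
* The Moran variance uses the normality closed form; for heavily skewed
  responses prefer the reported permutation p-value.
* Suitability values at locality cells are taken as error-free; no
  errors-in-variables correction is applied to the regressions.
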