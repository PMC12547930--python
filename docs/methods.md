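# Methods

This note documents the models, conventions and numerical choices the
package implements, in enough detail to reproduce or modify any stage.

## Problem and pipeline overview

Daily image guidance in prostate radiotherapy (here helical MVCT on
TomoTherapy-like delivery; a kilovoltage planning CT before treatment)
produces serial images of the rectum at no extra cost.  The package
asks whether texture changes in the rectal wall during treatment
predict grade >= 1 late rectal bleeding at two years, and — if so — by
which treatment week the prediction has stopped improving, which is the
natural time point for adaptive re-planning.  The pipeline is:

1. rasterise the rectum contour on each slice, build the 2-pixel wall
   ring, and tile 8x8 subimages along it;
2. compute 118 intensity/texture features per subimage and average over
   all subimages and slices of a scan;
3. average MVCT scan vectors into weekly time points (CT, W1..W7 for
   74 Gy / 37 fractions; CT, W1..W4 for 60 Gy / 20 fractions);
4. per regimen: a stratified 75:25 split, training-set z-scoring, a
   Mann-Whitney screen, Spearman redundancy pruning, an elastic-net
   logistic regression tuned by 5-fold cross-validated AUC, bootstrap
   AUC confidence intervals and Youden operating points;
5. compare time points with one-sided rank tests on the bootstrap AUC
   samples and select the earliest time point that no later time point
   significantly beats.

## Region of interest

The rectal wall is `mask - erode2(mask)`: two binary erosions with a
3x3 square structuring element, the standard discrete reading of a
"2-pixel inward expansion" of the contour.  If the double erosion
empties the mask (rectum thinner than ~4 px) the whole mask is used and
a warning logged.  Contours are rasterised with a centre-inclusive
rule: a pixel belongs to the polygon iff its centre (integer (row,
col)) is inside or on the boundary.

One 8x8 window is generated per wall pixel (1-pixel intervals along the
ring).  The window is placed so that the generating wall pixel lies in
the central 2x2 block, oriented by the local outward normal: the
erosion depth (1 or 2) and a 5x5 background-count estimate of the
outward direction decide, per axis, whether the window's central slot
is row 3 or row 4, so that where the wall is locally axis-normal the
window spans exactly 3 background pixels + the 2-pixel band + 3
interior pixels.  Anchors are de-duplicated and ordered row-major;
windows that would cross the slice border are dropped rather than
padded, because padding would inject artificial texture.  The choice of
one window per wall pixel (rather than per boundary-arc step) affects
only how many windows enter the average, not the averaging itself.

## Feature catalogue (118)

Family sizes are FOS 23, GLCM 25, GLRLM 16, GLSZM 16, GLDZM 16,
NGTDM 5, NGLDM 17 — the standard cardinalities of these families, which
sum to the catalogue total.  Features are addressed as `FAMILYk`
(1-based); `rwradiomics.catalogue` maps every code to its identifier
and exports the listing as CSV.

Conventions, fixed and unit-tested:

* **Discretisation**: fixed bin number over each subimage's own
  min-max range, default Ng = 8 (64 pixels -> ~8 per level); a constant
  subimage maps to level 1.  Discretisation per subimage makes all
  discretised families invariant to affine intensity rescaling.
* **FOS**: moments, order statistics and dispersion measures use the
  raw intensities (population variance; Fisher excess kurtosis;
  percentiles by linear interpolation).  Mode, entropy (bits),
  uniformity and the four histogram-gradient features use the
  discretised histogram.  Zero-variance conventions: skewness =
  kurtosis = coefficient of variation = 0.
* **GLCM**: distance 1, four directions, symmetric, normalised per
  direction; 25 features per direction, averaged over directions
  ("averaged" aggregation).  For a symmetric matrix the two
  information-correlation cross entropies reduce to twice the marginal
  entropy, which the implementation uses.  Constant image: correlation
  and both information correlations are 0.
* **GLRLM**: four directions, feature-level averaging.
* **GLSZM/GLDZM**: zones are 8-connected components of constant level;
  the GLDZM distance is the minimum chessboard distance of zone pixels
  to the outside of the 8x8 window (border pixels = 1), i.e. the window
  acts as the ROI border.
* **NGTDM/NGLDM**: 8-neighbourhoods using the neighbours that exist
  (no padding); NGLDM coarseness parameter alpha = 0 and dependence
  count = 1 + number of equal-level neighbours.  NGTDM coarseness of a
  constant image saturates at 1e6.

The batch extractor is a vectorised implementation of the same
definitions (co-occurrences and runs by composite-key bin counting,
zones by labelling a gap-separated canvas, entropies by integer count
lookup tables); it is tested element-for-element against the
single-subimage path and against exhaustive brute-force enumeration
oracles for all six matrix families.

## Temporal aggregation

Scan-level vectors are unweighted means over all subimages and slices.
Week maps: 74 Gy, weeks 1-6 = fractions 5(k-1)+1..5k, week 7 =
fractions 31-37; 60 Gy, four 5-fraction weeks.  Missing fractions are
tolerated: week averages use the available fractions (logged); a
patient with an entirely missing week has missing cells and is dropped
from models at that time point (logged roster).  Columns are named
`TP:FAMILYk` (e.g. `W1:FOS1`).

## Modelling

* **Split**: per regimen, test size = round-half-up(0.25 N) with
  round-half-up(0.25 n_pos) positives — the unique rounding rule that
  reproduces both reference splits (110 -> 82/28 with 8/20
  positive/negative test patients, 77 -> 58/19 with 8/11).
* **Standardisation**: training-set mean and population SD; constant
  training features are dropped with a log entry.
* **Screen**: two-sided Mann-Whitney U per feature (exact enumeration
  when both classes have <= 8 members and no ties; otherwise the
  tie-corrected normal approximation).  The screen ranks features and
  feeds the pruning tie-break; it drops nothing itself.
* **Pruning**: all pairs with training |Spearman rho| >= 0.8 are
  processed in descending |rho| (ties lexicographic); the member with
  the larger screen p is removed (ties: the lexicographically later
  name); pairs with an already-removed member are skipped.  The final
  set is asserted, on every run, to contain no pair at or above the
  threshold.
* **Elastic net**: logistic regression, L1 ratio 0.5, 500 log-spaced C
  values in [1e-4, 1e3], stratified seeded 5-fold CV scored by AUC.
  The path is fit per fold with warm-started saga at tol 1e-3 (CV
  scoring depends only on score rankings); the final refit uses
  tol 1e-5.  Any C whose path fit exhausts its iteration budget in some
  fold is excluded from selection, with a log entry.
* **Honest CV for C tuning**: in separate-analysis mode the screen and
  the Spearman prune use the training labels, so repeating them on the
  full training set and then cross-validating on those same rows would
  let every validation fold leak into the selection and inflate the CV
  curve (the selection bias of Ambroise & McLachlan, PNAS 2002; on
  pure-noise designs we observed whole CV curves sitting near AUC 0.7).
  The C-tuning CV therefore re-runs screen + prune inside each fold on
  that fold's training rows only.  The reported model is unchanged:
  features are selected once on the full training set and the final
  refit uses them at the chosen C.
* **Selection guard**: C = argmax mean fold AUC (ties -> strongest
  penalty), accepted only if that AUC exceeds 0.5 by at least 3.09
  standard errors (~0.1 % level, chosen for the 500-point path over
  which the maximum is taken).  Otherwise the model collapses to the
  closed-form intercept-only solution (intercept = training log-odds).
  The maximum of even an honest 500-point CV curve is upward biased, so
  an unguarded argmax fits pure noise and produces spurious, highly
  dispersed test AUCs; the guard is what makes the pipeline's null
  behaviour calibrated (see the tests) at the cost of ignoring true
  signals too weak to clear chance by that margin.  A small residual
  false-accept rate remains (the fold-scatter SE understates the
  variance of a path maximum), so occasional near-chance models still
  pass the guard on null data.
* **Evaluation**: AUC via the rank-sum identity (ties 0.5, equivalent
  to pair counting); 100 stratified bootstrap resamples give percentile
  95 % CIs; the Youden threshold is chosen on training scores (ties ->
  the lower threshold, favouring sensitivity) and applied unchanged to
  the test set.
* **Comparisons**: one-sided Mann-Whitney U on the two models' 100
  bootstrap AUC samples, without continuity correction so that
  p(a>b) + p(b>a) = 1.  Because bootstrap samples are cheap replicas
  rather than independent fits, this test is deliberately sensitive;
  with B = 100 even small AUC differences register as significant.
* **Optimal week**: the earliest time point t such that no later time
  point's training-AUC bootstrap distribution beats t's at p < 0.05.
  A final-week selection is annotated as having limited practical
  utility.  The rule is exposed as a function so alternatives can be
  plugged in.
* **Coefficient p-values**: Wald p-values from an unpenalised refit on
  the support selected by the elastic net (reported as such; they are
  descriptive, not selection-corrected).

Cumulative-mode designs at week w are the union of the separate-mode
pruned selections at CT and weeks 1..w; the design column set is
monotone in w by construction.

## Synthetic phantom cohort

The generator emulates the cohort structure the analysis assumes: two
regimens (default mix 59 % / 41 % of 74 Gy/37F and 60 Gy/20F, counts
rounded deterministically), ~33 % endpoint prevalence, a planning scan
plus one MVCT per fraction, 5 slices of 64x64 px per scan.

Each slice holds a filled, mildly deformed disc (the rectum, radius
drawn per patient from 8-14 px, jittered per fraction) on a flat
background.  The 2-pixel wall band carries
`mu_wall + s_i * field + noise`, where `field` is white noise smoothed
with a Gaussian of length `corr_length` (default 2 px) and normalised
to unit variance *on the band* — the band holds few effective degrees
of freedom of a correlated field, and normalising on it makes the
painted texture variance exactly the intended `s_i^2` instead of a
noisy realisation of it.  Patient texture SD is
`sigma_texture * exp(tau z - tau^2/2)` with `tau = 0.1` (log-normal
between-patient heterogeneity).  Daily images add more noise than the
planning image (`sigma_mvct = 8` vs `sigma_ct = 4` HU).

**Effect model**: for endpoint-positive patients the field variance is
multiplied by `1 + delta * ramp(week)` and the correlation length by
`1 + 0.25 * delta * ramp(week)`, with
`ramp(w) = min(1, max(0, (w - w0 + 1)/2))`: the effect appears at onset
week `w0` (default 1) at half strength and saturates one week later.
The planning scan is week 0 and never carries the effect; `delta = 0`
is an exact null.  The effect acts on texture variance and spatial
correlation because those are the properties the wall-heterogeneity
hypothesis points at, and they are the properties the FOS and
zone/co-occurrence families respectively recover.

**Parameter balance**: the defaults put the subimage variance budget
mostly into wall texture (wall/background contrast 10 HU, texture SD
20 HU) so that class separation is carried by the texture effect rather
than by incidental geometry.  With a large structural contrast the
radius-driven variation in window composition dominates between-patient
feature variance and buries any realistic texture effect — an early
finding that fixed these defaults.

**What the phantom does not emulate**: real pelvic anatomy, motion and
filling changes, scanner-specific noise spectra and artefacts,
inter-observer contouring variation, dose-response coupling, and
correlations between geometry and outcome.  Passing the recovery tests
shows the pipeline's machinery is correct and calibrated, not that the
clinical effect exists or is detectable at any particular size in real
MVCT data.

## Problem sizes used by the test suite and acceptance script

The repeat-based suites run the full pipeline on a scaled-down phantom:
120 patients, all 60 Gy/20F (one regimen keeps the whole cohort in one
model), one slice per scan, rectum radii 5-7 px, and only the scans
feeding the evaluated time points.  Twenty seeded repeats are used for
the null-calibration and signal-recovery rates (the acceptance script
uses 10 and 8); the optimal-week and pruning checks run on full
treatment courses.  These sizes keep a complete run to a few seconds
per cohort while leaving every stage of the method identical to a
full-scale run.

## Known limitations

* 2D slice-wise analysis only; no volumetric ROI or 3D texture.
* No image registration or dose accumulation; no shape/size features.
* The per-coefficient p-values come from an unpenalised refit and
  ignore selection; they describe, not test.
* Bootstrap AUC comparisons treat resamples as samples of a model's
  AUC; with B = 100 the comparison is sensitive to tiny differences,
  which makes the optimal-week rule conservative about early weeks.
* The selection guard trades sensitivity to weak true signals for null
  calibration; lower `guard_z` if screening weak effects matters more
  than false-positive models.
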