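# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## 1. Tumor/stroma recognition on TMA cores

The pipeline operates on RGB 8-bit core images and produces three binary
masks (tumor, stroma, whole core) with TSR = |stroma| / |core|.

**Grayscale.** Rec.601 luminance weights (0.299, 0.587, 0.114). The choice
of luminance triple is a convention; Rec.709 weights change the gradient
magnitudes by a few percent and none of the downstream thresholding
logic.

**Gradient.** Horizontal + vertical Sobel convolutions with edge
replication at the border; magnitude is the Euclidean norm. Only the Sobel
operator is used for contour detection; if the original workflow combined
a second edge operator, that is a possible (undocumented) deviation.

**Tumor objects.** The gradient map is thresholded, then
dilate → fill-holes → erode with a disc of `struct_radius` (default 5 px
at the 512-px fixture scale), and connected components smaller than
`min_object_area` (default 200 px²; expressed in µm² when the pixel size
is known) are eliminated. Two refinements proved necessary and are the
package's own design:

- *Gradient floor* (`gradient_floor`, default 100 in 8-bit Sobel units,
  i.e. requiring ≈25 grey levels of local contrast): Otsu on a gradient
  map always returns some threshold, so on images with no DAB-grade
  contours it promotes noise or the faint core-rim ramp to "edges", whose
  closed ring then fills the whole core. On the fixtures, rim gradients
  stay below ≈60 and nest-boundary gradients exceed ≈200, so the floor
  sits in a wide gap and is inactive whenever real contours exist.
- *Small-object elimination applied to contour fragments as well as final
  objects*: a nucleus produces a closed edge ring of a few dozen pixels,
  far below any nest-boundary ring (hundreds to thousands). Removing
  sub-threshold fragments before dilation prevents neighbouring nucleus
  rings from merging into super-threshold objects during dilation, which
  otherwise biases the TSR downward by several percent at realistic
  nucleus densities. Removal after erosion is retained, so both the
  monotonicity of tumor area in `min_object_area` and the
  "suitable threshold removes nuclei" behaviour hold.

A side effect of the morphological chain is a ≈1-px outward inflation of
each recognized nest (the gradient band straddles the true edge), a
sub-percent bias at fixture scale. Nests with boundary rings smaller than
`min_object_area` (radius ≲ 15 px at defaults) would be discarded; the
fixture nest radii (20–55 px) sit well above this.

**Whole-core mask.** CK-stained cores have up to three intensity modes:
dark tumor, off-white stroma, bright glass. A plain two-class Otsu on the
(equalized) grayscale therefore tends to isolate *tumor* rather than
*tissue* — after histogram equalization every class occupies an intensity
band proportional to its population, so the dominant class gets split.
The implementation instead evaluates the two-class Otsu threshold and the
three-class multi-Otsu pair as candidate tissue/background splits, on both
the raw and the equalized histogram, anchors the background class to the
frame border (a TMA core is surrounded by glass; a candidate is admissible
only if ≤ 5% of border pixels fall on its tissue side), and takes the most
inclusive admissible tissue mask. Holes are filled and components smaller
than `core_min_area_frac` (default 0.05) of the frame are dropped; all
surviving components are kept, tolerating fragmented cores. A frame with
no admissible split (e.g. blank glass) raises "no core detected".

**Composition.** The tumor mask is clipped to the core mask before the
ratio, stroma is the remainder of the core, and the overlay colours tumor
magenta, stroma cyan and non-cell black. A specimen's TSR is the maximum
over its cores (the field of highest stromal percentage).

## 2. Synthetic core images

The generator emulates the features the pipeline keys on: a circular core
(radius 0.45 × frame) whose rim fades to glass over ≈3 px; brown tumor
(150, 100, 55), pinkish off-white stroma (235, 222, 218), near-white glass
(246, 245, 244), blue nuclei (70, 70, 150) drawn inside stroma at
`nucleus_density` speckles per 1000 core pixels; i.i.d. Gaussian sensor
noise (σ = 3 grey levels). Colours are package constants chosen to mimic
DAB/hematoxylin appearance and are overridable per spec.

Tumor geometry is a union of discs around seed points clustered near a
random focus, mimicking a coherent lobulated invasive front. The union's
size is set by a single signed-distance offset chosen exactly on the
sorted distance transform, so the realized stromal fraction matches the
target to within one pixel shell (and always within the ±0.03 contract).
Clustered growth (rather than independent scattered nests) is deliberate:
at low stromal fractions, independently scattered overlapping nests
enclose stroma pockets, which *any* fill-holes-based recognizer — and the
recognizer described here — must misclassify as tumor; confluent tumor
sheets with peripheral stroma are also what low-stroma cores look like.

Not emulated: stromal fiber texture, staining gradients and artefacts
(folds, bubbles), nucleus clustering, out-of-focus blur, pyramidal
whole-slide context. Passing accuracy tests on these fixtures shows the
algorithmic chain is correct and well-calibrated at realistic geometry
and contrast; it does not certify performance on scanner images.

## 3. Synthetic cohorts

Covariates are drawn independently at the development cohort's marginal
frequencies (n = 240 table); independence is forced because only marginals
are published. Event times are exponential proportional hazards:
T ~ Exp(λ₀ · exp(Σ β)) with per-level log-hazards defaulting to the log of
the published multivariable HRs, administrative censoring at 60 months and
no other loss to follow-up. The default baseline rate λ₀ is not a magic
number: it is solved at generation time so that the *marginal* 5-year
disease-free survival equals the cohort's 62.0% — the linear predictor has
a discrete distribution over the 288 covariate patterns, so
E[exp(−60 λ₀ e^η)] is computed exactly and inverted by Brent's method.
The continuous TSR is drawn uniformly within the low/high segment of the
sampled TSR group (cutoff 0.555), so dichotomization reproduces the group.
Event times use inverse-transform sampling, making the event fraction
monotone in λ₀ under a fixed seed.

## 4. Cutpoint search

Candidates are midpoints between consecutive distinct marker values; a
split is admissible if both groups hold ≥ `min_group_frac` (default 0.10,
the X-tile convention) of the cohort. The two-group log-rank statistic is
evaluated for every admissible split via prefix-cumulated risk/death
tables (O(k·n) for k event times), which matches lifelines' statistic to
machine precision; equal statistics break toward the smallest cutoff. The
raw best P is anti-conservative by construction; the Miller–Siegmund
approximation for maximally selected statistics is reported alongside it
and clamped to ≥ the raw P. In null simulations (n = 200, 500 replicates)
the corrected P rejects ≈3% at the 5% level while the raw P rejects ≈40%.
The two-cutpoint search scores every admissible ordered pair by the
three-group log-rank chi-square (closed-form 2×2 covariance inversion,
vectorized over the second cutoff); ties resolve to the lexicographically
smallest pair. Marker values equal to a cutoff fall in the lower group.

## 5. Survival statistics

Pearson chi-square is uncorrected — that dialect, not the Yates-corrected
one, reproduces the published association P values (0.031 / 0.244 / 0.090)
from the printed counts. Fisher's exact test (two-sided, hypergeometric)
is the fallback when a 2×2 expected cell count is below 5. Kaplan–Meier
and the log-rank test are delegated to lifelines; curves report only
observed times (S(0) = 1 is implied). The Cox partial likelihood uses the
**Breslow** ties convention to match the original SPSS analyses; since
lifelines implements Efron ties, the Breslow fit is implemented directly
(Newton–Raphson with step-halving; Wald CIs from the inverse observed
information; Breslow baseline cumulative hazard at the reference pattern).
lifelines' Efron fitter remains available (`ties="efron"`) and serves as
an independent cross-check: on tie-free data the two agree to < 1e-4.
Stepwise selection at α = 0.10 uses likelihood-ratio tests both to enter
(forward) and to remove (backward); the LR entry test replaces the score
test sometimes used for entry — it is asymptotically equivalent, needs no
extra machinery beyond candidate fits, and selected identical models on
every fixture examined. Non-convergence and separation raise an explicit
diagnostic; zero-variance covariates are excluded with a warning. Strata
without events in the subgroup forest are reported as undefined (their
confidence intervals would be unbounded).

## 6. Nomogram

Points are computed from natural-log hazard ratios; within each predictor
the lowest-risk level is the zero point, and the largest within-predictor
span across predictors is scaled to 100 points. Points are kept at full
precision internally and rounded to one decimal only for display. The
scaling is scale-invariant in the coefficients (multiplying all β by c > 0
leaves points unchanged) and the score is a lossless affine image of the
linear predictor, so survival prediction through the nomogram equals the
Cox prediction to numerical tolerance. Applied to the published HR table,
the scaling reproduces the published point list within ±0.5 (consistent
with HRs printed to 3 decimals): T2 65.4 vs 65.1, T3 86.7 vs 87.0,
N+ 93.2 vs 93.4, grade II 27.0 vs 27.3, grade III 100.0, HER2+ 49.4 vs
49.6, stroma-high 30.5 vs 30.8. The printed ER points (36.34) are not
reproducible from the printed ER HR (the scaling gives 39.1); the
discrepancy is noted and ER is excluded from point-reproduction checks.

Validation utilities: Harrell's C (ties in score count ½, via lifelines);
calibration by equal-count bins of predicted S(t) with per-bin
Kaplan–Meier and Greenwood 95% CIs (degenerate constant predictions
collapse to a single usable bin); ROC comparison at a fixed horizon with
DeLong's paired test, where the binary outcome is "event by 60 months" and
patients censored before the horizon are excluded (their status is
unknown; this censoring dialect is a documented choice). Risk
stratification delegates to the two-cutpoint search on total points and
assigns groups I/II/III with the ≤/> convention.

## 7. Problem sizes and determinism

Default verification sizes: 512-px fixtures; 20 cores for the imaging
accuracy suite; n = 500 (9 replicates) for planted-cutoff recovery;
n = 2000 for Cox parameter recovery and calibration self-consistency;
500 replicates at n = 200 for the null cutpoint simulation. Every
stochastic component is driven by an explicit seed (NumPy Generator);
fixed seeds give byte-identical images and tables. The planted-cutoff
check asserts the median recovered cutoff over a fixed block of replicate
seeds, because a single maximally-selected cutoff estimate has sampling
spread comparable to the ±0.05 tolerance itself.

## 8. Known limitations

- The published cohort-level numbers that depend on the undeposited
  240-patient dataset (cutoff 55.5%, C-index 0.817, AUC 0.870 vs 0.723,
  KM χ² = 4.659, subgroup HRs) cannot be reproduced; the corresponding
  machinery is verified by parameter recovery, oracle equivalence and
  self-consistency instead.
- Colour deconvolution, whole-slide formats, nucleus counting, H&E-based
  TSR scoring, time-varying covariates, competing risks and
  optimism-corrected (bootstrap) validation are out of scope.
- Covariate independence in the cohort generator ignores any real
  correlation structure (only marginals are published), which makes
  parameter recovery easier than it would be on correlated data.
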