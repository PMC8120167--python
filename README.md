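# tsrnomo

Computerized assessment of the **tumor-stromal ratio (TSR)** on
CK/DAB-stained tissue-microarray (TMA) core images, and the downstream
survival superstructure for invasive breast cancer: best-P-value
dichotomization of the TSR, association tests, Cox proportional-hazards
modelling, and a points-based prognostic nomogram for 5-year disease-free
survival (5-DFS) with full validation (C-index, calibration, ROC, risk
stratification).

The intended users are digital-pathology and biostatistics researchers who
want a tested, scriptable implementation of this workflow. Because no
image or cohort data accompany the published analyses, the package ships
first-class synthetic generators that emulate both the stained-core
appearance (brown DAB tumor nests, off-white stroma, blue hematoxylin
nuclei, glass background) and the cohort's statistical structure, so every
stage can be exercised end to end with known ground truth.

## The methods

**TSR from a core image.** The recognition pipeline converts the RGB core
image to grayscale, computes the Sobel gradient magnitude to outline
object contours, thresholds it (Otsu on the gradient with an absolute
contour floor), applies dilate → fill → erode with a disc element, and
eliminates small objects (the critical knob: stromal nuclei would
otherwise be recognized as tumor). The whole-core mask comes from
Otsu-based tissue/background segmentation with the background class
anchored to the frame border. With stroma = core \ tumor,

    TSR = area(stroma) / area(core) = stroma / (tumor + stroma),

and a specimen's TSR is the **highest** stromal fraction over its cores.

**Cutpoint search.** The continuous TSR is dichotomized at the cutoff
maximizing the two-group log-rank statistic over all admissible splits
(X-tile's best-P principle), with the Miller–Siegmund corrected P reported
alongside the anti-conservative raw P. A two-cutpoint grid search
maximizing the three-group log-rank statistic yields risk groups I/II/III.

**Nomogram.** From a Cox model fit (Breslow ties, stepwise selection at
α = 0.10), each predictor level is assigned points

    points(level) = 100 · (β_level − min β within predictor) / max-span(β),

so the largest within-predictor log-hazard span equals 100 points, and

    S(t | x) = S₀(t)^exp(total points / points-per-unit-β + offset)

reproduces the Cox prediction exactly.

## Worked example

```python
from tsrnomo import ImageSpec, CohortSpec, generate_core_image, generate_cohort
from tsrnomo import assess_core, assess_specimen, PrognosticModel

# --- imaging: one synthetic core with 60% true stroma -------------------
pixels, truth = generate_core_image(ImageSpec(seed=7, true_stroma_frac=0.60,
                                              nucleus_density=1.0))
res = assess_core(pixels)
print(truth.true_tsr, res.tsr)        # 0.600 0.590
print(res.areas)                      # {'tumor': 67871, 'stroma': 97522, 'core': 165393}

# --- survival: synthetic 240-patient cohort -----------------------------
df = generate_cohort(CohortSpec(n_patients=240, seed=11))
fit = PrognosticModel.from_dataframe(df).fit(selection="backward")
print(fit.summary())
print(fit.c_index())                  # 0.782
strata = fit.stratify()
print(strata.cutoffs)                 # (194.0, 294.4) -> groups I/II/III
print(fit.nomogram.predict_survival(300, 60))   # 0.113
```

The summary lists, per predictor level, the log-hazard coefficient, hazard
ratio with Wald 95% CI and P, and the nomogram points (largest span scaled
to 100). On this seed, backward selection at α = 0.10 drops PR status and
retains T stage, N status, grade, ER, HER2 and the TSR group — the same
six predictors the nomogram uses. The C-index of 0.782 and the monotone
drop of predicted 5-DFS with total points (0.993 at 0 points vs 0.113 at
300) show the fitted score discriminating as designed.

The same workflow is available from a shell:

```sh
tsrnomo synth image --out imgs --n 4 --seed 5 --stroma-frac 0.6
tsrnomo assess --input imgs --out tsr.csv --overlays overlays
tsrnomo synth cohort --out cohort.csv --n 240 --seed 11
tsrnomo cutpoint --table cohort.csv --marker tsr
tsrnomo nomogram fit --table cohort.csv --out nomo.json
tsrnomo nomogram stratify --table cohort.csv
```

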