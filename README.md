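# calfmfi

Quantification of lower-leg fat distribution and muscle fat infiltration
(MFI) from axial T2-weighted MR images, with a fully synthetic phantom
cohort for end-to-end validation.

Fat infiltration in skeletal muscle accompanies declining muscle strength,
while excess subcutaneous and bone-marrow fat are implicated in metabolic
and bone disease. On T2-weighted images fat is bright relative to lean
muscle, so the calf-muscle pixel-intensity histogram carries a quantitative
fat signal without DIXON-style fat/water separation (which performs poorly
in muscle due to fiber-orientation effects). This package implements, as a
tested pipeline, the measurement chain a musculoskeletal imaging group
would run on such data:

1. **Bias-field correction** — multiplicative coil-shading removal, either
   by N4 (via SimpleITK) or by a self-contained robust log-domain
   polynomial fit over the leg mask.
2. **Morphometry** from label masks. Subcutaneous fat thickness per slice
   is the annulus area over the mean of its boundary lengths,

   ```
   SFT = (1/7) Σᵢ 2Aᵢ / (L1 + L2)ᵢ ,   i over the 7 central slices (2–8 of 9)
   ```

   with sub-pixel contour lengths; fibula bone-marrow area (BMA) is the
   marrow pixel count × pixel area, averaged over the same slices.
3. **Histogram MFI indexes** — the muscle-ROI histogram (peripheral calf
   muscle inferior to the fibula centroid), averaged over the central
   slices and normalized to ∫y dx = 100, is fitted with a Gaussian or an
   asymmetric pseudo-Gaussian whose linewidth varies linearly with
   intensity, FWHM(x) = a + b·x (Gaussian at b = 0). Features: mean
   intensity, mode intensity (argmax of the fitted curve), full linewidth
   at half height, and Pearson skewness (mean − mode)/sd.
4. **Severity grading** — features are z-scored; PCA ranks them by summed
   absolute loadings over the components explaining ≥95 % of variance; the
   top two (mean and mode intensity) feed Fuzzy C-Means,

   ```
   J = Σᵢ Σⱼ uᵢⱼᵐ ‖xᵢ − vⱼ‖²,   Σⱼ uᵢⱼ = 1
   ```

   with m = 2 and 10 seeded restarts. Clusters are named
   normal / mild / moderate / severe in ascending centroid mean intensity;
   the cluster count is chosen among {3, 4, 5} as the largest candidate
   whose solution is linearly separable (ambiguity-aware LP test).
5. **Association statistics** — pooled-variance t-tests, Pearson
   correlations, OLS fits of each outcome on age + BMI with an overall
   F-test, crossed over sex and obesity (BMI ≥ 30) strata, plus a
   repeatability-noise robustness procedure (each measurement perturbed at
   its segmentation CV; battery p-values averaged over 10 executions).
   No multiple-testing correction is applied; p-values are reported raw.

Because clinical images cannot be redistributed, the package ships a
first-class synthetic-phantom module: a parametric leg cross-section
(subcutaneous annulus, fibula with cortical rim and marrow disk, muscle bed
with spatially clumped fat marbling at an exactly planted fat fraction),
rendered into 9-slice stacks at 0.7 × 0.7 mm² with multiplicative bias and
noise, together with cohort-level generators that plant sex-specific SFT /
BMA distributions, a four-level severity mixture and covariate slopes.
Every pipeline stage is validated against this planted truth.

## Worked example

```python
from calfmfi.phantom import SubjectTruth, generate_subject
from calfmfi.bias import correct_stack
from calfmfi.morphometry import measure_subject
from calfmfi.histogram import mfi_features_for_subject

truth = SubjectTruth("S001", "F", age=50.0, bmi=28.0, true_sft=8.9,
                     true_bma=35.7, true_fat_fraction=0.15,
                     severity_class="mild")
stack, masks = generate_subject(truth)
morph = measure_subject(masks, "S001")
feats, profile, fit = mfi_features_for_subject(correct_stack(stack, masks),
                                               masks)
print(f"SFT  = {morph.sft_mm:.2f} mm, BMA = {morph.bma_mm2:.2f} mm^2")
print(f"mean = {feats.mean_intensity:.1f}, mode = {feats.mode_intensity:.1f}, "
      f"FWHM = {feats.fwhm:.1f}, skewness = {feats.skewness:.3f}")
```

prints

```
SFT  = 8.84 mm, BMA = 34.79 mm^2
mean = 146.7, mode = 102.9, FWHM = 49.3, skewness = 0.586
```

The planted 8.9 mm ring thickness is recovered to 0.7 % by the mask-based
morphometry (the residual is rasterization error); the 15 % muscle fat
fraction lifts the ROI histogram mean to ≈ 100 + 300 × 0.15 a.u. and skews
it to the right (mean > mode), exactly the signature the MFI indexes are
designed to capture.

The same chain runs from the shell:

```
calfmfi run-all --out run/            # full default cohort (107 subjects)
calfmfi simulate --out cohort/        # or stage by stage
calfmfi correct-bias --in cohort/ --method polynomial
calfmfi measure --manifest cohort/manifest.csv --out morphometry.csv
calfmfi mfi --manifest cohort/manifest.csv --out mfi_features.csv
calfmfi cluster --features mfi_features.csv --c auto --out severity.csv
calfmfi associate --measurements merged.csv --out report.csv
```

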