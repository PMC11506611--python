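# Methods

This note documents the models, numerical choices and validation design of
`calfmfi` in the package's own terms: what is computed, under which
assumptions, and what the synthetic-phantom experiments do and do not
demonstrate.

## Phantom model

A subject is a 9-slice axial stack (256 × 256 pixels, 0.7 mm in-plane,
6 mm slice-centre spacing) of an idealized leg cross-section:

* **leg** — a disk of outer radius `leg_radius` (default 45 mm, enlarged
  per subject when a large planted SFT/BMA would not otherwise fit);
* **subcutaneous fat** — an annulus of exactly the planted thickness
  (`true_sft`); the thickness is held constant across slices while the leg
  radius varies smoothly by ≤3 %, so the central-slice average is a
  meaningful estimate of one planted value;
* **fibula** — a cortical ring (2 mm) around a marrow disk of exactly the
  planted area (`true_bma`), at a fixed offset from the leg centre;
* **muscle** — the remaining interior, carrying fat marbling.

Intensities are arbitrary units chosen to preserve T2w contrast ordering:
background 5, cortical bone 20, lean muscle 100, fat (subcutaneous and
marrow) 400. Only the fat ≫ muscle ordering matters for the histogram
analysis; the 4:1 ratio makes the fat signal unambiguous at the default
noise level (σ = 15 a.u., i.e. SNR ≈ 7 in muscle).

**Marbling.** Fat infiltration is modelled as a per-pixel fat partial
volume g ∈ [0, 1] over the muscle bed: a Gaussian random field smoothed to
correlation length `clump_scale` (2 mm) is passed through a logistic soft
threshold (width 0.35 field-sd units) whose offset is solved by bisection
so that the mean of g over the muscle mask equals the planted fat fraction
to 1e-12. The soft edge emulates partial-volume mixing at clump
boundaries; it is what makes the histogram *mode* (not just the mean)
respond monotonically to the fat fraction, as observed on real images.
Setting the softness to 0 recovers hard binary patches of exactly the
planted pixel count; setting the fat fraction to 0 yields exactly lean
muscle (useful as a degenerate test case).

**Bias and noise.** A smooth multiplicative field is planted per subject —
a random second-order polynomial in normalized coordinates, scaled to peak
fractional deviation `bias_amplitude` (0.2) and normalized to mean 1 over
the leg so it reshapes rather than rescales tissue intensities (matching
the corrector's normalization contract; otherwise every subject would
carry an arbitrary random intensity gauge). Noise is additive Gaussian
clipped at zero by default; a Rician switch is provided, and at the SNRs
used the distinction is immaterial to the histogram features.

**Cohorts.** Per-sex truth distributions default to the study population
the phantom emulates: 64 males / 43 females; SFT 4.3 ± 2.2 mm (M) vs
8.9 ± 3.7 mm (F), floored at 1 mm; BMA 35.7 ± 21.1 mm² (M) vs
32.6 ± 20.0 mm² (F), floored at 5 mm² (the smallest disk that rasterizes
acceptably); ages and BMIs from per-sex truncated normals within the
printed ranges. Severity is a four-level mixture at 42/42/14/2 % with
per-class muscle fat fractions 0.05/0.15/0.30/0.60; the default allocation
is exact largest-remainder counts (45/45/15/2 at n = 107), reproducing the
emulated cohort's composition, with a multinomial option. Linear covariate
slopes (e.g. SFT falling with age in men, rising with BMI in women) can be
planted per sex; the residual sd is shrunk so the marginal sd stays at its
configured value. Below-floor draws are redrawn and counted.

For the validation cohorts used by the acceptance experiments, truths are
drawn by stratified inverse-CDF sampling (shuffled equal-probability
stratum midpoints). This is a standard variance-reduction design: the
experiments measure *measurement fidelity* — whether the pipeline recovers
the planted population mean — and stratification removes the Monte-Carlo
error of the planted sample itself, which at n = 43–64 would otherwise be
of the same order as the effect under test. The generator default remains
iid. Note that flooring at 1 mm shifts the male SFT truncated-normal mean
from 4.30 to ≈ 4.60 mm; the recovery experiments are assessed against the
population values at ±2 standard errors, which covers this truncation
shift.

## Bias-field correction

The default estimator fits a total-degree-3 polynomial to the log image
over the leg mask and exponentiates; the field is normalized to mean 1
over the mask so correction preserves mean tissue intensity. A plain
least-squares fit would absorb the fat/muscle/cortex contrast into the
"field" (measured on phantoms: muscle CV *increases* six-fold), so the fit
is restricted to one tissue plateau: pixels within 0.65 log units of the
30th-percentile log intensity (an anchor that stays inside muscle even
when a thick subcutaneous ring dominates the leg area), refined once
against the fitted surface with a ±0.5 band. These bands pass the full
bias variation (|log field| ≲ 0.3 at the default amplitude) plus noise
while rejecting the ≈1.4-log-unit fat/muscle contrast. On a clean phantom
the muscle CV is reduced ~200-fold and re-estimation on a corrected image
returns a field within machine precision of unity. The fit subsamples at
most 20 000 mask pixels. `method="n4"` delegates to SimpleITK's N4 with
its default hyper-parameters.

## Morphometry

Boundary lengths are sub-pixel: contours at the 0.5 iso-level of a
σ = 1 px Gaussian-smoothed mask. Marching squares on the raw binary mask
overestimates a circle's perimeter by ~5 %, which would bias SFT low by
the same amount; with smoothing the error is < 1 % at the radii involved.
The outer boundary is traced on the hole-filled annulus and the inner
boundary on the hole itself, so 1–2-px-thin annuli (low-SFT males) remain
measurable. Annulus area is pixel count × pixel area. For an annulus of
constant thickness t, 2A/(L1+L2) = t exactly (also for parallel-curve
bands around convex shapes); rasterization keeps the measurement within
2–3 %.

The muscle ROI is the muscle mask strictly inferior to the fibula centroid
row (centroid over cortex + marrow, rounded half-down), emulating the
horizontal dividing line used in manual protocols; a < 100-pixel ROI emits
a warning but is still returned. `perturb_mask` emulates manual-redraw
variability by thresholding the signed distance transform displaced by a
smooth random field (sd = `magnitude` pixels, smoothing 4 px), retrying up
to 5 times if the component/hole counts change; 1 px of jitter yields an
SFT repeatability CV of a few percent, the order reported for repeated
manual segmentations.

Pixel-count areas of small disks fluctuate at the percent level with
sub-pixel alignment: halving the pixel size changes a 78.5 mm² disk's
measured area by < 1 %, but a 35 mm² disk (radius ≈ 3.3 mm ≈ 4.8 px) can
shift by ~2 %. Cohort-level BMA means inherit only the sub-percent part of
this because alignments vary across subjects.

## Histogram analysis

Per-slice ROI histograms (default bin width 2 a.u., roughly 200 bins over
the phantom intensity range) are averaged pointwise on a shared grid and
normalized so the trapezoidal integral is exactly 100, making profiles
comparable across subjects. The lineshape y(x) = h·exp(−4 ln 2 (x −
x₀)²/FWHM(x)²) with FWHM(x) = a + b·x is fitted by bounded least squares;
internally the linear width is parametrized by its values at the support
endpoints, so box bounds keep FWHM(x) > 0 over the whole support (the
reported intercept a can then legitimately be negative at x = 0 for
strongly widening fits — x = 0 lies outside the fitted support).
Initialization is deterministic (raw argmax, raw half-height span, b = 0),
and the Gaussian model is the exact b = 0 restriction, so the
pseudo-Gaussian residual can never exceed the Gaussian one.

Features mix two sources by design: mean and sd are moments of the raw
normalized profile (robust to lineshape misfit), while the mode and FWHM
come from the fitted curve evaluated on a 10×-refined grid (robust to bin
noise at the peak). A `moments="fitted"` flag computes mean/sd from the
fitted curve instead. Pearson skewness is (mean − mode)/sd. Features are
stable to bin-width halving within 2 %.

## Severity clustering

Features are z-scored per column; PCA (full SVD, loadings sign-fixed so
each component's largest-magnitude entry is positive) keeps the smallest
number of components reaching 95 % cumulative explained variance and
scores each feature by its summed absolute loadings; the top two are
retained. On phantom cohorts these are the mean and mode intensities. Two
degenerate facts about this importance score are worth recording: when a
pure-noise direction is itself a retained component its loading sum can
exceed that of correlated informative features, and for an exactly
spherical correlation matrix the loading basis (hence the score) is
arbitrary — the score discriminates only when the leading components are
genuinely shared.

Fuzzy C-Means is implemented from its alternating closed-form updates
(fuzzifier m = 2, tol 1e-5 on max |ΔU|, ≤1000 iterations, best of 10
seeded random-membership restarts by final objective; a coincident
point/centroid receives full membership there). The objective history is
non-increasing by construction and memberships are row-stochastic.

Cluster-count selection among {3, 4, 5} takes the largest candidate whose
solution is linearly separable; among separable solutions this is also the
one with the lowest objective. Separability of *hard* labels alone cannot
discriminate here: converged FCM hard labels are nearest-centroid
(Voronoi) partitions, and Voronoi cells are convex, so every such
labelling is linearly separable. The implemented test is therefore
ambiguity-aware: a point joins the convex hull of every cluster whose
membership is within 50 % of its top membership, so over-splitting a
genuine group (memberships ≈ 0.5/0.5 between the two sub-centroids) makes
the hulls overlap and rejects the candidate. Pairwise separation is
decided by exact LP feasibility of a unit-margin separating line, not a
trained classifier. `assess_separability` on user-supplied hard labels
keeps the plain LP semantics. Clusters are ordered by the centroid
mean-intensity coordinate (mode coordinate breaks ties) and named
normal/mild/moderate/severe at c = 4. A mean-only (single-feature)
clustering variant is supported and yields closely similar groupings on
planted cohorts, since the mean index dominates the separation.

## Statistics

Two-sample comparisons use the pooled-variance t-test (Welch by flag);
correlations are Pearson with the exact t-based p; multivariate fits are
OLS of outcome on age + BMI with the overall F-test as the primary p-value
and per-coefficient p-values alongside. The subgroup battery crosses
{whole group, sex, obesity (BMI ≥ 30), sex × obesity} with outcomes {SFT,
BMA, MFI mean, MFI mode}, predictors {age, BMI}, and the cross-
correlations of the MFI indexes with BMA and SFT — 144 rows; strata too
small for a test yield NA rows with a reason. No multiple-testing
correction is applied anywhere (each p is reported raw, as is conventional
in the descriptive analyses this battery reproduces); readers should
interpret marginal significances across the 144-row crossing accordingly.
The robustness procedure perturbs each measurement with zero-mean Gaussian
noise at its repeatability CV (defaults 3.0/3.4/3.2/4.1 % for
SFT/BMA/mean/mode), re-runs the battery 10 times and averages the
p-values; with CV = 0 it returns the noiseless battery unchanged. All
tests' type-I error is verified within Monte-Carlo tolerance
([0.035, 0.065] at α = 0.05 over 2000 null simulations).

## Validation design and problem sizes

The test suite and the acceptance script regenerate everything from seeds;
no data files ship with the package. Cohort-scale experiments use the
emulated study sizes (43 F / 64 M for the morphometry recovery, 107 for
severity recovery); single-slice and single-subject fixtures serve the
unit tests. A full cohort experiment takes tens of seconds on one CPU;
the complete suite runs in about a minute.

What passing these experiments shows: the measurement chain is unbiased at
the percent level against planted geometry, the histogram features respond
monotonically to planted fat fraction, the clustering recovers a planted
well-separated 4-level mixture essentially perfectly, and the statistical
battery is calibrated. What it does not show: performance under real
anatomy (non-circular legs, multiple muscle compartments, fascia), real
coil-shading shapes, Rician noise at low SNR, registration or motion
artifacts, or manual-segmentation bias — the phantom plants none of these,
and the severity classes are planted far enough apart that clustering
accuracy on real, continuously distributed MFI would be lower,
particularly at class boundaries.

## Known limitations

* Morphometry consumes ground-truth masks (or externally supplied ones);
  no intensity-based segmentation is provided.
* The fat-fraction scale is arbitrary-unit, not calibrated to physical
  fat percent.
* The tibia is not modelled; only the fibula marrow is measured.
* The polynomial bias corrector assumes a dominant tissue plateau covering
  a spatial majority of the mask interior; images without one (e.g.
  end-stage infiltration everywhere) degrade gracefully toward the N4
  delegate, which should then be preferred.
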