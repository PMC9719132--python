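# Methods

## Problem and pipeline

The package classifies a single post-acetic-acid cervix photograph as VIA
positive (acetowhite lesion present) or negative. The design is a classical
radiomics pipeline — deterministic preprocessing, a fixed hand-crafted
feature panel, unsupervised feature pruning, and a cross-validated choice
among standard classifiers — rather than a learned end-to-end model, so every
stage is auditable and testable in isolation.

## Synthetic scene generator

No clinical images ship with the package; the generator renders the minimal
geometry the pipeline exploits and nothing more:

- a cervix disk of radius 0.28–0.38 of the short image side, centered within
  4% jitter of the frame center, pink (RGB 195/110/135) against a darker
  brownish surround (70/50/55), with a 2-px soft edge;
- 3–8 specular glints of radius 5–12 px (about 1–3% of the 400×400 frame,
  typical of smartphone glare), painted after the noise stage with all
  channels ≥ 250 in the recorded core and a 1-px soft rim outside it;
- for positives, one soft-edged ellipse (Gaussian alpha falloff, semi-axes
  0.25–0.45 of the cervix radius) in matte acetowhite (232/214/214) carrying
  a blotchy low-frequency texture (Gaussian-filtered noise, σ = 2.5 px).

Rendering composes a noiseless mean field and a blended noise-σ field and
then draws a single Gaussian noise realization (σ = 8 on tissue), clipped to
[0, 255]. The blotch-texture amplitude is proportional to the Euclidean
distance between lesion and cervix mean colors (0.2 per unit). Both choices
serve one property: setting the lesion color equal to the cervix color makes
positive and negative scenes *statistically identical*, so the pipeline must
fall to chance — a built-in negative control. Conversely the default colors
give high contrast in both color and texture, so a correct pipeline should
approach perfect separation. Passing tests on these scenes therefore
demonstrates that the machinery recovers planted signal and does not
hallucinate absent signal; it says nothing about performance on real cervical
images, whose nuisance variation (pose, illumination, mucus, blood, speculum)
the generator deliberately omits.

Scene k of a dataset is seeded by a counter-based child of the master seed
(`SeedSequence(master, spawn_key=(k,))`, folded below 2³¹), so individual
scenes are reproducible independently of batch size. Labels are a seeded
permutation with exactly `round(n × prevalence)` positives; the default
prevalence 0.181 reflects a screening population of roughly one positive in
five-to-six examinations.

## Specular-reflection removal

The detector builds, per image, the average of three min-max-normalized
channels in which glints are jointly extreme: inverted HSV saturation, RGB
green, and CIE-Lab lightness (sRGB, D65, L rescaled to [0, 1]). A soft
emphasis rescales the [0.7, 1] tail of this average to [0, 1] and zeroes the
rest: tissue sits near 0.5 and background lower, so only near-specular pixels
survive. Without this step, sensor-noise response of the subsequent filter
forms a floor over the whole frame that exceeds the mean in-glint response
once glints are larger than the filter window. A 3×3 *population*
standard-deviation filter (edge replication at borders) then responds at
glint boundaries, and the result is min-max normalized with a constant-input
guard (constant → all zeros, so a uniformly white frame yields no
detections). The removal mask is `response > threshold` (default 0.5),
dilated by 1 px and hole-filled — the filter responds on the rim of a glint,
and filling the closed ring recovers its interior. Masked pixels are replaced
by iterative boundary-mean inpainting (each unknown layer takes the mean of
its known 8-neighbors). Glints overlapping the bright acetowhite patch have
low local contrast and are partially missed; that is a property of real
specularity on white lesions, not a defect the pipeline hides.

## ROI detection

Features are the per-pixel pair (R, a\*): R the Euclidean distance from the
image center ((H−1)/2, (W−1)/2) and a\* from CIE-Lab. Both are z-scored over
the image (spherical covariance needs comparable scales: R spans ~[0, 140],
a\* ~[−60, 60]). A 2-component Gaussian mixture with spherical covariances is
initialized from K-means (10 restarts, best inertia, seeded) and fitted by
EM; non-convergence raises an error carrying the iteration count. The cervix
is the component with the smallest mean R (most central), ties broken toward
larger mean a\* (redder); its pixel set is reduced to the largest 8-connected
component with holes filled. Two components suffice because the scene
decomposes into "central pink disk" vs "everything else"; the count is
configurable. The crop takes the mask's bounding box, pads each side by 5% of
the box dimension (rounded), clips to the image, and resizes bilinearly to
200×200; the mask is resized by nearest neighbor and carried into feature
extraction. An optional geometric-disk flag replaces the mask with the
equivalent-area disk at the mask centroid for strictly circular ROIs.

## Feature panel

75 features in a fixed, documented order (manifest exportable as JSON).
Gray conversion is luma 0.299R + 0.587G + 0.114B. The co-occurrence families
(GLCM, NGTDM, GLSZM) see an equal-width 16-level quantization of the masked
gray range (constant region → level 0); DWT and LBP operate on the unquantized
gray raster. Extraction requires ≥ 64 masked pixels and is NaN-free above
that floor.

- **Color (12):** mean and population std of R, G, B, G/(R+1), B/(R+1) and
  HSV value V = max(R,G,B)/255, over masked pixels. The +1 denominator guard
  (on 8-bit values) avoids division by zero and is recorded in the feature
  names.
- **GLCM (28):** symmetric normalized co-occurrence matrices at distance 1,
  directions 0°/45°/90°/135°, pairs counted only when both pixels are masked;
  14 Haralick statistics per direction, panel stores mean and range over
  directions. Degenerate conventions: correlation and the maximal correlation
  coefficient are 1 on a single-level region; the information measures fall
  back to 0 when their entropy denominators vanish; natural logarithms, 0·log 0 = 0.
- **NGTDM (5):** Amadasun–King coarseness, contrast, busyness, complexity,
  strength; 3×3 neighborhoods restricted to masked pixels; gray levels enter
  the formulas 1-based so the lowest level carries weight. Coarseness is
  capped at 10⁶ when Σ pᵢsᵢ = 0; contrast is 0 with fewer than two levels;
  busyness and strength are 0 when their denominators vanish.
- **GLSZM (14):** zones are 8-connected equal-level components within the
  mask. Statistics: small/large-zone emphasis, gray-level non-uniformity
  (+ normalized), size-zone non-uniformity, zone percentage, low/high
  gray-level zone emphasis, the four small/large × low/high combinations,
  gray-level variance and zone-size variance. The family is fixed at 14
  slots; among the two possible normalized non-uniformities only the
  gray-level one is included.
- **DWT (6):** one-level 2-D transform (Haar default, configurable); pixels
  outside the mask are set to the masked mean first so mask-boundary edges do
  not leak energy. Mean and population std of |coefficients| in LH, HL, HH,
  with HL pinned to the subband that responds to vertical edges.
- **LBP (10):** uniform local binary patterns, P = 8, R = 1 (9 uniform bins
  by number of set bits + 1 non-uniform bin), histogram over masked pixels
  with a complete in-frame neighborhood (frame pixels would compare against
  phantom zeros), normalized to sum 1.

## Selection and normalization

Zero-variance features (std ≤ 1e−12) are dropped first. The absolute Pearson
correlation matrix of the remaining training columns is scanned over its
upper triangle in panel order; when |r| exceeds the threshold (default 0.9)
and both columns are still alive, the later one is dropped, recording the
retained partner. Keeping the earlier column makes the rule deterministic and
order-stable. z-score parameters (mean, population std) are fitted on the
kept columns of the training rows only; `apply_selection` replays them on any
table, so held-out data never influences the transform.

## Classifier selection and evaluation

The nine candidate families — gradient boosting, logistic regression, random
forest, extra trees, Gaussian naive Bayes, AdaBoost, LightGBM, k-nearest
neighbors, decision tree — come from scikit-learn/LightGBM with library
default hyperparameters and pinned seeds; no hyperparameter search.
Cross-validation is stratified (25 folds by default; stratification is what
makes a fold-level recall constraint well-defined at screening prevalence)
with the pruning + z-scoring refit inside every training fold.
PrecisionAtRecall(m) is computed by exhaustive sweep over the distinct
held-out scores plus −∞, predicting positive at score ≥ t, and returns the
best precision among thresholds with recall ≥ m.

A caveat measured during development: with ~134 rows, 25 folds hold 5–6
samples each, and the fold-level null expectation of PrecisionAtRecall is
roughly E[1/rank] ≈ 0.4 rather than the prevalence — a small-sample bias of
the metric, not a leak. Permutation-null checks therefore use 5 folds, where
the null lands near prevalence.

Final training refits selection + estimator on the full training table and
stores the decision threshold (default 0.29) inside the persisted model
directory together with the selection state and pipeline config, so
prediction replays the identical chain: resize → specular removal → ROI →
crop → features → z-score → probability; label = score ≥ threshold. If ROI
detection fails on an input, prediction falls back to a whole-image ROI with
a warning instead of refusing.

Evaluation reports the confusion matrix at the stored threshold; sensitivity,
specificity, accuracy and precision to 3 decimals with undefined ratios
flagged as not-applicable; the ROC by threshold sweep over distinct scores;
AUC by the trapezoid rule (identical to the normalized Mann–Whitney U
statistic, which the tests assert to 1e−12); and a 95% CI from a seeded
stratified percentile bootstrap (2000 resamples, classes resampled
separately, interval clipped to [0, 1] and widened to bracket the point
estimate).

## Problem sizes

The study-shaped experiment uses 199 scenes at 400×400 (prevalence 0.181)
split 134/65 with 26/10 positives — a split that guarantees every
25-fold stratum contains a positive. ROI recovery uses 50 scenes; oracle
comparisons run on exhaustive small rasters (2×2 … 6×6, 3 gray levels)
against naive loop implementations kept separate from the production code.

## Known limitations

- The generator's realism is deliberately minimal (no speculum, mucus,
  blood, pose or illumination variation; single post-acetic frame only), so
  synthetic performance is an upper bound of machinery correctness, not a
  clinical claim.
- The 75-feature panel's exact statistic sets for GLCM/GLSZM and the
  quantization depth are pinned, documented conventions; other radiomics
  toolkits make different choices and will produce different numbers.
- Specular glints on top of bright lesions are under-detected by design of
  the contrast-based detector.
- The decision threshold 0.29 is stored, not re-optimized; changing the
  operating point requires retraining or editing the model directory.
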