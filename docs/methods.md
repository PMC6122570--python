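# Methods

## The estimator

The quantity of interest is the Ki67 index `T = 100 · n+ / (n+ + n−)`,
the percentage of Ki67-positive nuclei among all tumor nuclei in a
region of interest (ROI). `ki67area` estimates it without detecting
individual nuclei, via the positive-area fraction

```
A = 100 · S+ / (S+ + S−)
```

where `S+` and `S−` are the pixel areas of Ki67-positive and
Ki67-negative nucleus masks, intersected with a tumor mask. The
statistical link between `A` and `T` rests on one assumption: positive
and negative tumor nuclei are drawn from (near-)identical size
distributions. Writing `S+ = n+ · s̄+` with `s̄+` the mean positive
nucleus area, equal size distributions give `E[A] ≈ T`, so an ordinary
least squares calibration `T̂(A) = c1·A + c2` has slope `c1 ≈ 1` and the
intercept absorbs any residual size asymmetry (if positive nuclei run
systematically larger, `A` overshoots `T` and `c2` goes negative).
Calibrated predictions are clamped to [0, 100]; the raw line can dip
below zero for small `A`, which is not a meaningful percentage.

Whole-image variants (no tumor mask) are provided for comparison,
including quadratic and cubic recalibrations. When the contamination by
non-tumor nuclei varies from ROI to ROI, the whole-image `A` relates to
`T` through a per-ROI random scale factor, which no fixed polynomial in
`A` can invert — the reason within-tumor computation beats higher-order
whole-image models in every agreement metric.

## Segmentation

1. **Pixel clustering.** k-means (k = 3) on the RGB pixels, subsampled
   every 4th pixel for speed. Initial centers are chosen by
   farthest-point traversal starting at pixel index 0, making the fit
   deterministic for a given image. Centroids are role-tagged in
   L\*a\*b\*: highest L\* → background; of the remaining two, larger b\*
   (the yellow/brown direction) → DAB, the other → hematoxylin. Images
   with fewer than three distinct colors raise a degenerate-cluster
   error.
2. **Color transform.** Pixels are mapped to CIE L\*a\*b\* (sRGB, D65)
   and projected onto the unit vector from the hematoxylin centroid to
   the DAB centroid in the (a\*, b\*) chroma plane. L\* is excluded so
   staining *intensity* cannot masquerade as stain *identity*. The
   transform is stored as a 3×3 matrix whose first row is the
   projection axis; the axis is undefined (error) when the two
   centroids sit closer than 0.5 chroma units (well-stained H-DAB
   centroids are ~40 units apart).
3. **Entropy thresholding.** Kapur's maximum-entropy criterion on the
   projected nucleus pixels: 256 uniform histogram bins over the
   observed min–max, exhaustive evaluation of all interior cuts,
   maximizing the sum of Shannon entropies of the two partitions, ties
   broken toward the lower threshold. Pixels above the threshold are
   positive, the rest negative. Nucleus pixels are those not assigned
   to the background cluster and with L\* ≤ 90 (a guard against
   near-white pixels).
4. **Morphology.** Each mask gets hole filling, then removal of
   connected components smaller than 30 px; when hole filling makes the
   masks overlap, the positive label wins. No watershed splitting — the
   method's point is that per-nucleus identification is unnecessary.

**Two-step presence check.** Kapur thresholding *always* splits its
input, so an image with no DAB at all would have its bluest/brownest
hematoxylin pixels relabeled positive. To prevent this, segmentation
first classifies pixels against precomputed cluster centroids and a
precomputed transform (derived once from a fixed-seed synthetic
calibration set of 25 ROIs and shipped as a JSON fixture), thresholding
the precomputed projection at the midpoint between the projected
hematoxylin and DAB centroids. Only if at least `min_positive_px = 50`
pixels (≈ a quarter of a small nucleus; a literal one-pixel rule is
noise-fragile) survive on the DAB side after small-object removal does
the image-specific clustering run; otherwise the positive mask is
forced empty and negative nuclei are taken from the hematoxylin side of
the precomputed projection.

A note on Kapur's criterion with well-separated clusters: when the
projection histogram has a wide empty gap, the entropy sum is maximized
slightly *inside* the broader cluster rather than in the gap (nibbling
a low-mass sliver into the other partition raises its entropy at almost
no cost). With realistic, smooth within-cluster spread this sliver is a
few edge pixels and Dice scores stay ≥ 0.9; with artificially flat
per-nucleus colors it can swallow whole nuclei. This drove one
generator design choice below.

## The synthetic ROI generator

The generator emulates high-power-field crops of Ki67-stained breast
tissue with exact ground truth; defaults are chosen to look like a 40×
field:

- **Geometry**: 2300 × 1200 px default frame; elliptical nuclei with
  axes from a truncated normal (mean 14 px, sd 3 px, minimum 6 px),
  uniform orientation. Overlap is forbidden by default (rejection
  sampling, 1000 attempts per nucleus, failure raises an error naming
  the count achieved); an `allow` policy sums optical densities where
  nuclei overlap. Per-label size multipliers exist so the size-bias
  effect on the intercept can be simulated.
- **Stains**: Beer-Lambert optical-density mixing with the standard
  H-DAB unmixing vectors (hematoxylin ≈ (0.650, 0.704, 0.286), DAB ≈
  (0.269, 0.568, 0.778)); `RGB = 255·exp(−OD)` on a white background.
  Negative nuclei carry hematoxylin (0.90 OD); positive nuclei carry
  DAB (0.90) over a reduced hematoxylin counterstain (0.35).
- **Stain variability**: each stain amount receives an independent
  per-nucleus and per-pixel multiplicative jitter, uniform on
  ±15% by default. Independence matters: counterstain uptake and
  antibody-DAB deposition are separate processes, and coupling them
  with a single factor would make the DAB cluster implausibly narrow
  along the stain-identity axis — exactly the histogram shape that
  destabilizes entropy thresholding. At zero jitter a nucleus interior
  is perfectly flat.
- **Noise**: additive Gaussian per channel (sd 4 on the 0–255 scale),
  then clipping.
- **Non-tumor regions**: contiguous elliptical stroma blobs carved out
  of the tumor mask (target ~20% of the frame), populated with
  counterstained (by default all negative) nuclei. Dataset generation
  can draw the per-ROI non-tumor nucleus count as a uniform fraction of
  the tumor count (default range 0.1–0.6 in pipeline runs), so the
  contamination level varies across ROIs as it does across real fields.
- **Determinism**: one seeded generator per ROI; per-ROI seeds are
  drawn from the dataset seed and recorded in the manifest, so a
  dataset is reproducible byte-for-byte.

What the generator does **not** emulate: chromatin texture, out-of-focus
blur, touching/overlapping nuclei (under the default policy), uneven
illumination, stain variation across laboratories, and tissue
architecture beyond elliptical blobs. Passing tests therefore
demonstrate the internal consistency of the pipeline and the statistical
behavior of the area index under controlled conditions — not clinical
segmentation accuracy on real slides.

## Statistical conventions

- **RMSE**: plain `sqrt(mean(d²))` for raw estimates; the regression
  convention `sqrt(SSE/(n − p − 1))` (software "root MSE") for fitted
  models.
- **R² / adjusted R²**: from the OLS fit;
  `adj = 1 − (1 − R²)(n − 1)/(n − p − 1)`.
- **Coefficient CIs**: 95%, t-based.
- **Lin's CCC**: `2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)` with population
  (1/n) moments, per Lin's original definition. The CI uses the Fisher
  z-transform with Lin's asymptotic standard error, back-transformed
  and clipped to [−1, 1]; at |ccc| numerically 1 the interval
  degenerates to the point.
- **Bland-Altman**: differences are estimate − truth; bias is their
  mean; limits of agreement are bias ± 1.96 · sample SD (n − 1). After
  an OLS recalibration the bias is exactly 0 (zero-mean residuals) and
  the limits are symmetric about zero.

## Problem sizes

Tests and the acceptance script run on scaled-down frames — typically
600 × 320 px with 100 tumor nuclei (one-quarter linear scale of the
default frame at matched tissue density) and 240 × 160 to 420 × 240 px
for unit tests — with 40–75 ROIs per simulated study. The slope,
ordering and bias properties being checked are scale-free; sizes were
chosen as the smallest at which per-ROI sampling noise does not dominate
them.

## Known limitations

- The precomputed presence check is calibrated on synthetic staining;
  real-world deployment would regenerate the fixture from a
  laboratory's own slides (`scripts/make_precomputed.py` shows how).
- Kapur's criterion can misplace the cut when one stain population is
  extremely narrow (see above); stain normalization across institutions
  is out of scope.
- The area index deliberately does not recover nucleus *counts*;
  converting areas back to counts is future work.
- Heavily overlapping nuclei violate the generator's ground-truth
  assumptions; the `allow` overlap policy renders them but the masks
  then undercount the true area.
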