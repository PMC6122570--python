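# ki67area

Area-based estimation of the Ki67 proliferation index from
immunohistochemistry (IHC) images of breast tissue.

## The problem

The Ki67 index — the percentage of Ki67-positive malignant cells among
all malignant cells scored — is a prognostic biomarker in breast cancer,
but counting individual nuclei is slow, hard to automate reliably, and a
major source of inter-laboratory disagreement. `ki67area` implements an
estimator that skips nucleus detection entirely: it segments
Ki67-positive (DAB-brown) and Ki67-negative (hematoxylin-blue) *pixels*,
computes the positive-area fraction within tumor regions,

```
A = 100 · area(positive nucleus pixels) / area(all tumor-nucleus pixels)   [%]
```

and calibrates it to the count-based index `T` with a linear model

```
T̂(A) = c1 · A + c2
```

Because positive and negative tumor nuclei have near-identical size
distributions, `A` tracks `T` with slope `c1 ≈ 1`; the calibration only
absorbs a small constant offset. When non-tumor tissue (stroma rich in
counterstained nuclei) is included in the computation, the relationship
degrades and even a cubic recalibration cannot fully repair it — which is
why the index must be computed within tumor regions.

Segmentation works in three stages:

1. **k-means clustering** of RGB pixels into background / hematoxylin /
   DAB clusters;
2. a **CIE L\*a\*b\* color transform** that projects each pixel onto the
   hematoxylin→DAB axis in the (a\*, b\*) chroma plane;
3. **maximum-entropy (Kapur) thresholding** of the projected nucleus
   pixels to split positive from negative.

A two-step variant first checks — with precomputed cluster centroids and
a precomputed color transform — whether the image contains any DAB at
all; stain-free images get an empty positive mask instead of having
negative nuclei erroneously relabeled as positive.

Agreement between estimates and the truth is quantified with RMSE,
R²/adjusted R², Lin's concordance correlation coefficient (CCC) with
confidence intervals, and Bland-Altman bias with 95% limits of
agreement.

Since clinical slides are not distributable, the package ships a
synthetic IHC ROI generator (Beer-Lambert H-DAB stain rendering with
exact per-pixel ground truth) that every stage is tested against.

## Worked example

Run the full pipeline — generate 20 synthetic ROIs with randomly varying
non-tumor contamination, segment them, compute area indices in both
scopes, calibrate, and evaluate:

```bash
ki67 run --out demo --seed 11 --n-rois 20
```

`demo/model.json` then holds the within-tumor calibration

```
c1 = 1.005  (95% CI 0.977, 1.033)
c2 = 0.314  (95% CI -0.889, 1.518)
rmse = 1.339   R² = 0.9969
```

— slope ≈ 1: the area fraction is essentially the Ki67 index up to a
small offset. `demo/report.csv` compares the scopes:

```
  method variant  n   rmse   ccc    bias  loa_low  loa_high
A_within     raw 20  1.371 0.998  -0.501   -3.066     2.065
A_within  linear 20  1.339 0.998  -0.000   -2.555     2.555
 A_whole     raw 20 10.942 0.869  -8.516  -22.331     5.298
 A_whole   cubic 20  5.802 0.974   0.000  -10.436    10.436
```

The whole-image estimate underestimates the truth by 8.5 points on
average (the carved-in stroma regions are rich in negative nuclei) and a
cubic recalibration removes the bias but stays four times worse in RMSE
than the within-tumor linear model — the quantitative case for excluding
non-tumor regions rather than compensating with higher-order polynomials.

The steps are also available individually (`ki67 generate`,
`ki67 segment`, `ki67 index`, `ki67 calibrate`, `ki67 evaluate`), and
everything is importable as a library:

```python
from ki67area import ROISpec, generate_roi, segment_roi, compute_area_index

roi = generate_roi(ROISpec(n_positive=40, n_negative=60, seed=1))
masks = segment_roi(roi.image, tumor_mask=roi.tumor_mask)
print(compute_area_index(masks, tumor_mask=roi.tumor_mask).value)
```

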