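"""Segmentation pipeline: clustering, color transform, Kapur, presence check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ki67area import (ClusterModel, ROISpec, SegmentationConfig, cluster_pixels,
                      derive_color_transform, detect_positive_presence,
                      generate_roi, kapur_threshold, rgb_to_lab, segment_roi)
from ki67area.segmentation import ConstantInputError, DegenerateClusterError


def three_patch_image():
    """Flat patches of white, hematoxylin-blue and DAB-brown."""
    img = np.empty((30, 30, 3), dtype=np.uint8)
    img[:10] = (255, 255, 255)
    img[10:20] = (60, 70, 150)
    img[20:] = (130, 90, 50)
    return img


class TestRgbToLab:
    def test_white_point(self):
        lab = rgb_to_lab((255, 255, 255))
        assert lab[0] == pytest.approx(100.0, abs=1e-6)
        assert abs(lab[1]) < 0.01 and abs(lab[2]) < 0.01

    def test_black(self):
        assert np.allclose(rgb_to_lab((0, 0, 0)), (0.0, 0.0, 0.0), atol=1e-9)

    def test_matches_independent_conversion(self):
        # hand-coded sRGB -> XYZ (D65) -> L*a*b*, independent of skimage
        def reference_lab(rgb):
            c = np.asarray(rgb, float) / 255.0
            c = np.where(c > 0.04045, ((c + 0.055) / 1.055) ** 2.4, c / 12.92)
            M = np.array([[0.4124564, 0.3575761, 0.1804375],
                          [0.2126729, 0.7151522, 0.0721750],
                          [0.0193339, 0.1191920, 0.9503041]])
            xyz = M @ c
            wp = np.array([0.95047, 1.0, 1.08883])
            t = xyz / wp
            f = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
            return np.array([116 * f[1] - 16,
                             500 * (f[0] - f[1]),
                             200 * (f[1] - f[2])])

        for rgb in [(130, 90, 50), (60, 70, 150), (10, 200, 128)]:
            assert np.allclose(rgb_to_lab(rgb), reference_lab(rgb), atol=5e-3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_lab((300, 0, 0))
        with pytest.raises(ValueError):
            rgb_to_lab((-1, 0, 0))


class TestClusterPixels:
    def test_three_flat_patches_recovered_with_roles(self):
        model = cluster_pixels(three_patch_image(), subsample=1)
        assert np.allclose(sorted(model.centroids.tolist()),
                           sorted([[255, 255, 255], [60, 70, 150], [130, 90, 50]]))
        assert np.allclose(model.centroid("background"), (255, 255, 255))
        assert np.allclose(model.centroid("hematoxylin"), (60, 70, 150))
        assert np.allclose(model.centroid("dab"), (130, 90, 50))

    def test_all_white_image_is_degenerate(self):
        img = np.full((20, 20, 3), 255, dtype=np.uint8)
        with pytest.raises(DegenerateClusterError):
            cluster_pixels(img)

    def test_dab_centroid_near_rendered_positive_color(self, noiseless_roi):
        model = cluster_pixels(noiseless_roi.image, seed=0)
        rendered = noiseless_roi.image[noiseless_roi.gt_positive_mask].mean(axis=0)
        assert np.linalg.norm(model.centroid("dab") - rendered) < 10.0

    def test_determinism(self, noiseless_roi):
        a = cluster_pixels(noiseless_roi.image, seed=0)
        b = cluster_pixels(noiseless_roi.image, seed=0)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.roles == b.roles


class TestColorTransform:
    def test_projection_orders_dab_above_hematoxylin(self):
        model = cluster_pixels(three_patch_image(), subsample=1)
        tr = derive_color_transform(model)
        p_h = tr.project(rgb_to_lab(model.centroid("hematoxylin")))
        p_d = tr.project(rgb_to_lab(model.centroid("dab")))
        assert p_d > p_h
        assert tr.projection_axis[0] == 0.0  # L* excluded
        assert np.linalg.norm(tr.projection_axis) == pytest.approx(1.0)

    def test_coincident_chroma_rejected(self):
        # two grays share (a*, b*) = (0, 0): no stain axis exists
        model = ClusterModel(
            np.array([[255, 255, 255], [100, 100, 100], [140, 140, 140]]),
            ("background", "hematoxylin", "dab"),
        )
        with pytest.raises(DegenerateClusterError):
            derive_color_transform(model)


def kapur_brute_force(values, n_bins=256):
    """Exhaustive search over all cut-points: the oracle for kapur_threshold."""
    v = np.asarray(values, float).ravel()
    hist, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    p = hist / hist.sum()
    best, best_t = -np.inf, None
    for t in range(n_bins - 1):
        s0, s1 = p[:t + 1].sum(), p[t + 1:].sum()
        if s0 <= 0 or s1 <= 0:
            continue
        q0 = p[:t + 1][p[:t + 1] > 0] / s0
        q1 = p[t + 1:][p[t + 1:] > 0] / s1
        psi = -(q0 * np.log(q0)).sum() - (q1 * np.log(q1)).sum()
        if psi > best + 1e-12:
            best, best_t = psi, t
    return float(edges[best_t + 1])


class TestKapurThreshold:
    def test_two_point_sample_separates_cleanly(self):
        vals = np.array([50.0] * 10 + [200.0] * 10)
        thr = kapur_threshold(vals)
        assert 50.0 < thr < 200.0
        assert np.all(vals[vals <= thr] == 50.0)
        assert np.all(vals[vals > thr] == 200.0)

    def test_constant_sample_rejected(self):
        with pytest.raises(ConstantInputError):
            kapur_threshold(np.full(10, 7.0))

    def test_bimodal_matches_exhaustive_search(self):
        rng = np.random.default_rng(42)
        vals = np.concatenate([rng.normal(60, 5, 300), rng.normal(180, 5, 100)])
        assert kapur_threshold(vals) == pytest.approx(kapur_brute_force(vals))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(rng.uniform(-50, 50), rng.uniform(1, 30),
                          rng.integers(10, 400))
        if vals.max() == vals.min():
            return
        assert kapur_threshold(vals) == pytest.approx(kapur_brute_force(vals))


class TestPresenceCheck:
    def test_all_negative_roi_has_no_positive_presence(self, precomputed):
        roi = generate_roi(ROISpec(n_positive=0, n_negative=30,
                                   width=240, height=160, seed=4))
        assert detect_positive_presence(roi.image, precomputed) is False

    def test_positive_roi_detected(self, precomputed):
        roi = generate_roi(ROISpec(n_positive=30, n_negative=10,
                                   width=300, height=200, noise_sd=0.0, seed=5))
        assert detect_positive_presence(roi.image, precomputed) is True

    def test_blank_white_image(self, precomputed):
        img = np.full((60, 80, 3), 255, dtype=np.uint8)
        assert detect_positive_presence(img, precomputed) is False


class TestSegmentROI:
    def test_dice_against_ground_truth(self, noiseless_roi, precomputed, dice_fn):
        masks = segment_roi(noiseless_roi.image, precomputed=precomputed)
        assert not masks.used_precomputed
        assert dice_fn(masks.positive_mask, noiseless_roi.gt_positive_mask) >= 0.90
        assert dice_fn(masks.negative_mask, noiseless_roi.gt_negative_mask) >= 0.90

    def test_zero_positive_roi_yields_empty_positive_mask(self, precomputed):
        roi = generate_roi(ROISpec(n_positive=0, n_negative=30,
                                   width=240, height=160, seed=8))
        masks = segment_roi(roi.image, precomputed=precomputed)
        assert masks.used_precomputed
        assert masks.positive_px == 0
        assert masks.negative_px > 0

    def test_blank_white_image_yields_empty_masks(self, precomputed):
        img = np.full((60, 80, 3), 255, dtype=np.uint8)
        masks = segment_roi(img, precomputed=precomputed)
        assert masks.positive_px == 0 and masks.negative_px == 0

    def test_masks_disjoint_and_contained_in_tumor_mask(self, precomputed):
        roi = generate_roi(ROISpec(n_positive=15, n_negative=15, n_nontumor=10,
                                   width=300, height=200, seed=6))
        masks = segment_roi(roi.image, tumor_mask=roi.tumor_mask,
                            precomputed=precomputed)
        assert not np.any(masks.positive_mask & masks.negative_mask)
        assert not np.any(masks.positive_mask & ~roi.tumor_mask)
        assert not np.any(masks.negative_mask & ~roi.tumor_mask)

    def test_shape_mismatch_rejected(self, noiseless_roi, precomputed):
        bad = np.zeros((10, 10), dtype=bool)
        with pytest.raises(ValueError, match="shape"):
            segment_roi(noiseless_roi.image, tumor_mask=bad, precomputed=precomputed)

    def test_positive_area_monotone_in_dab_amount(self, precomputed):
        # same geometry (same seed/spec apart from stain amounts), rising DAB
        from ki67area import StainProfile

        areas = []
        for dab in (0.3, 0.6, 0.9, 1.2):
            spec = ROISpec(n_positive=15, n_negative=15, width=300, height=200,
                           noise_sd=0.0, stain_intensity_jitter=0.0, seed=9,
                           stains=StainProfile(positive_dab=dab))
            roi = generate_roi(spec)
            areas.append(segment_roi(roi.image, precomputed=precomputed).positive_px)
        assert all(a <= b for a, b in zip(areas, areas[1:]))

    def test_threshold_within_observed_range(self, noiseless_roi, precomputed):
        from ki67area.segmentation import derive_color_transform, cluster_pixels

        masks = segment_roi(noiseless_roi.image, precomputed=precomputed)
        model = cluster_pixels(noiseless_roi.image, seed=0)
        proj = derive_color_transform(model).project(rgb_to_lab(noiseless_roi.image))
        assert proj.min() <= masks.threshold_value <= proj.max()
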