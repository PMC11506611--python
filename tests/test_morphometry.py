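"""Morphometry: boundary lengths, SFT, BMA, muscle ROI, mask perturbation."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from calfmfi.morphometry import (CENTRAL_SLICES, MaskTopologyError,
                                 boundary_lengths, compute_bma, compute_sft,
                                 derive_muscle_roi, perturb_mask)
from tests.conftest import annulus_mask, disk_mask


class TestBoundaryLengths:
    def test_circle_perimeter_within_2pc(self):
        # disk of radius 20 px at 0.7 mm/px: perimeter 2*pi*14 = 87.96 mm
        mask = annulus_mask(10, 20, shape=(128, 128))
        _, outer = boundary_lengths(mask, 0.7)
        assert outer == pytest.approx(2 * np.pi * 14.0, rel=0.02)

    def test_inner_shorter_than_outer(self):
        # annulus r_inner 50 mm, r_outer 55 mm at 1 mm pixels
        mask = annulus_mask(50, 55, shape=(160, 160))
        l1, l2 = boundary_lengths(mask, 1.0)
        assert l1 < l2
        assert l1 == pytest.approx(2 * np.pi * 50, rel=0.02)
        assert l2 == pytest.approx(2 * np.pi * 55, rel=0.02)

    def test_lengths_scale_with_pixel_size(self):
        mask = annulus_mask(20, 30, shape=(128, 128))
        l1a, l2a = boundary_lengths(mask, 0.7)
        l1b, l2b = boundary_lengths(mask, 1.4)
        assert l1b == pytest.approx(2 * l1a) and l2b == pytest.approx(2 * l2a)

    def test_non_annular_masks_rejected(self):
        with pytest.raises(MaskTopologyError, match="hole"):
            boundary_lengths(disk_mask(20), 0.7)  # no hole
        two_holes = annulus_mask(20, 40, shape=(160, 160)).copy()
        two_holes[disk_mask(3, shape=(160, 160), center=(79.5, 109.0))] = False
        with pytest.raises(MaskTopologyError, match="hole"):
            boundary_lengths(two_holes, 0.7)
        two_comp = np.zeros((128, 128), bool)
        two_comp[annulus_mask(5, 10, shape=(128, 128), center=(30, 30))] = True
        two_comp[annulus_mask(5, 10, shape=(128, 128), center=(90, 90))] = True
        with pytest.raises(MaskTopologyError, match="component"):
            boundary_lengths(two_comp, 0.7)


class TestComputeSFT:
    def test_circular_annulus_recovers_thickness(self):
        # thickness 5 mm = 50 px at 0.1 mm pixels, and 2A/(L1+L2) = t exactly
        masks = {s: annulus_mask(40 / 0.7, 45 / 0.7, shape=(256, 256))
                 for s in CENTRAL_SLICES}
        sft, detail = compute_sft(masks, 0.7)
        assert sft == pytest.approx(5.0, rel=0.02)
        assert len(detail) == 7

    def test_subject_value_is_slice_mean(self):
        # one thinner slice: SFT = (4 + 6*5)/7
        thick = annulus_mask(40 / 0.7, 45 / 0.7, shape=(256, 256))
        thin = annulus_mask(41 / 0.7, 45 / 0.7, shape=(256, 256))
        masks = {s: (thin if s == 2 else thick) for s in CENTRAL_SLICES}
        sft, detail = compute_sft(masks, 0.7)
        assert sft == pytest.approx(np.mean([v[0] for v in detail.values()]))
        assert sft == pytest.approx((4 + 6 * 5) / 7, rel=0.02)

    def test_elliptical_annulus_constant_normal_thickness(self):
        # parallel-curve band of an ellipse (constant normal thickness t)
        # built on a 4x supersampled grid, then block-averaged to pixels
        f = 4
        n = 256 * f
        rr, cc = np.mgrid[0:n, 0:n]
        ctr = (n - 1) / 2.0
        outer = ((rr - ctr) / (90.0 * f)) ** 2 + (
            (cc - ctr) / (60.0 * f)
        ) ** 2 <= 1.0
        t_px = 7.0
        band = outer & ~(ndimage.distance_transform_edt(outer) > t_px * f)
        annulus = band.reshape(256, f, 256, f).mean(axis=(1, 3)) >= 0.5
        sft, _ = compute_sft({s: annulus for s in CENTRAL_SLICES}, 0.7)
        assert sft == pytest.approx(t_px * 0.7, rel=0.03)

    def test_slice_order_irrelevant(self):
        base = annulus_mask(40 / 0.7, 45 / 0.7, shape=(256, 256))
        thin = annulus_mask(42 / 0.7, 45 / 0.7, shape=(256, 256))
        masks = {s: (thin if s % 2 else base) for s in CENTRAL_SLICES}
        shuffled = {s: masks[s] for s in (5, 2, 8, 3, 7, 4, 6)}
        assert compute_sft(masks, 0.7)[0] == compute_sft(shuffled, 0.7)[0]

    def test_failing_slice_named(self):
        masks = {s: annulus_mask(30, 40) for s in CENTRAL_SLICES}
        masks[5] = disk_mask(30)
        with pytest.raises(MaskTopologyError, match="slice 5"):
            compute_sft(masks, 0.7)

    def test_wrong_slice_set_rejected(self):
        masks = {s: annulus_mask(30, 40) for s in (1, 2, 3, 4, 5, 6, 7)}
        with pytest.raises(ValueError, match="slices"):
            compute_sft(masks, 0.7)


class TestComputeBMA:
    def test_planted_disk_within_3pc(self):
        # the phantom's own planted 36 mm^2 marrow disk
        from calfmfi.phantom import PhantomSpec, rasterize_slice

        spec = PhantomSpec(marrow_area=36.0)
        _, masks = rasterize_slice(spec, 1, np.random.default_rng(0))
        bma, detail = compute_bma(
            {s: masks["marrow"] for s in CENTRAL_SLICES}, spec.pixel_size
        )
        assert bma == pytest.approx(36.0, rel=0.03)
        assert len(detail) == 7

    def test_empty_mask_rejected(self):
        masks = {s: disk_mask(4) for s in CENTRAL_SLICES}
        masks[3] = np.zeros((128, 128), bool)
        with pytest.raises(ValueError, match="empty"):
            compute_bma(masks, 0.7)

    def test_refinement_convergence_on_example_disk(self):
        # same physical 78.5 mm^2 disk rasterized at 0.7 and 0.35 mm pixels
        from calfmfi.phantom import PhantomSpec, rasterize_slice

        vals = []
        for ps, size in ((0.7, 256), (0.35, 512)):
            spec = PhantomSpec(marrow_area=78.5, pixel_size=ps,
                               image_size=(size, size))
            _, masks = rasterize_slice(spec, 1, np.random.default_rng(0))
            vals.append(
                compute_bma({s: masks["marrow"] for s in CENTRAL_SLICES}, ps)[0]
            )
        assert abs(vals[1] - vals[0]) / vals[0] < 0.01

    def test_area_scales_with_pixel_size_squared(self):
        masks = {s: disk_mask(10) for s in CENTRAL_SLICES}
        assert compute_bma(masks, 1.4)[0] == pytest.approx(
            4 * compute_bma(masks, 0.7)[0]
        )


class TestMuscleROI:
    def test_no_pixel_at_or_above_centroid_row(self):
        muscle = np.ones((200, 200), bool)
        fibula = disk_mask(10, shape=(200, 200), center=(90.0, 100.0))
        roi = derive_muscle_roi(muscle, fibula)
        rows = np.nonzero(roi)[0]
        assert rows.min() > 90

    def test_matches_brute_force_pixel_scan(self):
        rng = np.random.default_rng(0)
        muscle = rng.random((120, 120)) > 0.4
        fibula = disk_mask(8, shape=(120, 120), center=(55.3, 60.1))
        roi = derive_muscle_roi(muscle, fibula)
        rows = np.nonzero(fibula)[0]
        cut = int(np.ceil(rows.mean() - 0.5))
        expected = np.array(
            [[muscle[r, c] and r > cut for c in range(120)] for r in range(120)]
        )
        assert np.array_equal(roi, expected)

    def test_empty_roi_warns(self):
        muscle = np.zeros((100, 100), bool)
        muscle[:20] = True  # everything superior to the fibula
        fibula = disk_mask(5, shape=(100, 100), center=(60, 50))
        with pytest.warns(UserWarning, match="ROI"):
            roi = derive_muscle_roi(muscle, fibula)
        assert roi.sum() == 0

    def test_empty_fibula_rejected(self):
        with pytest.raises(ValueError, match="fibula"):
            derive_muscle_roi(np.ones((50, 50), bool), np.zeros((50, 50), bool))


class TestPerturbMask:
    def test_zero_magnitude_identity(self, rng):
        mask = annulus_mask(20, 30)
        assert np.array_equal(perturb_mask(mask, 0.0, rng), mask)

    def test_same_seed_same_perturbation(self):
        mask = annulus_mask(20, 30)
        p1 = perturb_mask(mask, 1.0, np.random.default_rng(7))
        p2 = perturb_mask(mask, 1.0, np.random.default_rng(7))
        assert np.array_equal(p1, p2)

    def test_topology_preserved(self, rng):
        mask = annulus_mask(20, 30)
        for _ in range(5):
            p = perturb_mask(mask, 1.0, rng)
            filled = ndimage.binary_fill_holes(p)
            assert ndimage.label(p)[1] == 1
            assert ndimage.label(filled & ~p)[1] == 1

    def test_repeat_segmentation_cv_is_a_few_percent(self):
        # 1 px boundary jitter on the SF annulus: SFT repeatability CV of
        # order a few percent, comparable to manual-redraw variability
        from calfmfi.stats import reproducibility_cv

        rng = np.random.default_rng(42)
        mask = annulus_mask(40 / 0.7, 45 / 0.7, shape=(256, 256))
        sfts = []
        for _ in range(5):
            p = perturb_mask(mask, 1.0, rng)
            sft, _ = compute_sft({s: p for s in CENTRAL_SLICES}, 0.7)
            sfts.append(sft)
        cv = reproducibility_cv(sfts)
        assert 0.1 < cv < 10.0

    def test_negative_magnitude_rejected(self, rng):
        with pytest.raises(ValueError):
            perturb_mask(annulus_mask(20, 30), -1.0, rng)
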