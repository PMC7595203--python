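import numpy as np
import pytest

import lungdfi.roi as R
from lungdfi.forward import SystemConfig
from lungdfi.phantom import HEALTHY_LUNG


class TestPresmooth:
    def test_constant_image_is_fixed_point(self):
        img = np.full((20, 20), 7.0)
        np.testing.assert_allclose(R.presmooth(img, 3.0), img, atol=1e-12)

    def test_impulse_mass_conserved(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = R.presmooth(img, 2.0)
        assert abs(out.sum() - 1.0) < 1e-9

    def test_checkerboard_variance_strictly_decreases(self):
        yy, xx = np.mgrid[0:32, 0:32]
        board = ((yy // 1 + xx // 1) % 2).astype(float)
        out = R.presmooth(board, 3.0)
        assert out.var() < board.var()

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            R.presmooth(np.zeros((4, 4)), 0.0)


class TestSegmentBone:
    def test_recovers_ground_truth_bone(self, healthy_phantom, healthy_modalities):
        mask = R.segment_bone(
            healthy_modalities.absorption,
            body_mask=healthy_phantom.anatomy_masks["body"],
        )
        gt = healthy_phantom.anatomy_masks["bone"]
        jaccard = (mask & gt).sum() / (mask | gt).sum()
        assert jaccard >= 0.8

    def test_image_below_threshold_gives_empty_mask(self):
        img = np.full((32, 32), 0.2)
        assert not R.segment_bone(img, threshold=1.0).any()

    def test_morphology_stage_is_idempotent(self, rng):
        """A binary opening applied twice equals applying it once."""
        from scipy.ndimage import binary_dilation, binary_erosion
        from skimage.morphology import disk
        blob = rng.random((64, 64)) > 0.45

        def opening(m):
            e = binary_erosion(m, structure=disk(1), iterations=2)
            return binary_dilation(e, structure=disk(1), iterations=2)

        once = opening(blob)
        np.testing.assert_array_equal(opening(once), once)

    def test_larger_radius_never_adds_pixels(self, healthy_modalities, healthy_phantom):
        body = healthy_phantom.anatomy_masks["body"]
        prev = None
        for r in (1, 2, 3):
            mask = R.segment_bone(healthy_modalities.absorption, threshold=1.9, morph_radius=r,
                                  body_mask=body)
            if prev is not None:
                assert not np.any(mask & ~prev)
            prev = mask


class TestMeanSignal:
    def test_constant_image(self):
        mask = np.zeros((10, 10), bool)
        mask[2:7, 3:8] = True
        assert R.mean_signal(np.full((10, 10), 5.0), mask) == 5.0

    def test_arithmetic_mean(self):
        img = np.arange(1.0, 101.0).reshape(10, 10)
        assert R.mean_signal(img, np.ones((10, 10), bool)) == pytest.approx(50.5)

    def test_empty_mask_error_names_roi(self):
        with pytest.raises(ValueError, match="left lung of M007"):
            R.mean_signal(np.ones((4, 4)), np.zeros((4, 4), bool), "left lung of M007")

    def test_noiseless_control_lung_recovers_calibration(self, healthy_phantom, healthy_modalities):
        """End-to-end noiseless: control-lung absorption mean == 0.788."""
        masks = R.build_lung_masks(healthy_modalities, healthy_phantom.anatomy_masks)
        q = R.quantify_animal(healthy_modalities, masks, "healthy")
        assert q.control_absorption == pytest.approx(HEALTHY_LUNG[0], abs=1e-6)
        assert q.control_darkfield == pytest.approx(HEALTHY_LUNG[1], abs=1e-6)
        assert q.transplanted_absorption == pytest.approx(HEALTHY_LUNG[0], abs=1e-6)

    def test_noisy_recovery_within_centiband(self, healthy_phantom, modalities_of):
        """Poisson noise at N0 = 1e4: ROI means within 0.01 of the targets."""
        cfg = SystemConfig(noise="poisson", photons_per_pixel=1e4)
        m = modalities_of(healthy_phantom, cfg, rng=np.random.default_rng(123))
        masks = R.build_lung_masks(m, healthy_phantom.anatomy_masks)
        q = R.quantify_animal(m, masks, "healthy")
        assert abs(q.control_absorption - HEALTHY_LUNG[0]) < 0.01
        assert abs(q.control_darkfield - HEALTHY_LUNG[1]) < 0.01
        assert abs(q.transplanted_darkfield - HEALTHY_LUNG[1]) < 0.01

    def test_identical_pixel_sets_for_both_modalities(self, healthy_phantom, healthy_modalities):
        masks = R.build_lung_masks(healthy_modalities, healthy_phantom.anatomy_masks)
        q = R.quantify_animal(healthy_modalities, masks, "x")
        assert q.n_pixels_transplanted == masks.transplanted_mask.sum()
        assert q.n_pixels_control == masks.control_mask.sum()


class TestDetectPneumothorax:
    def test_pneumothorax_detected(self, pneumothorax_phantom, modalities_of):
        m = modalities_of(pneumothorax_phantom)
        assert R.detect_pneumothorax(m, pneumothorax_phantom.anatomy_masks["left_lung"])

    def test_healthy_not_flagged(self, healthy_phantom, healthy_modalities):
        assert not R.detect_pneumothorax(
            healthy_modalities, healthy_phantom.anatomy_masks["left_lung"]
        )

    def test_atelectasis_not_mistaken_for_pneumothorax(self, truncation_phantom, modalities_of):
        """Total atelectasis: dark-field is low but absorption is high."""
        m = modalities_of(truncation_phantom)
        left = truncation_phantom.anatomy_masks["left_lung"]
        assert np.nanmean(m.darkfield[left]) < 0.3
        assert np.nanmean(m.absorption[left]) > 0.5
        assert not R.detect_pneumothorax(m, left)

    def test_mask_disjointness_enforced(self):
        a = np.zeros((4, 4), bool); a[0, 0] = True
        with pytest.raises(ValueError):
            R.LungMasks(transplanted_mask=a, control_mask=a, bone_mask=np.zeros((4, 4), bool))
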