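"""Normalisation, resampling, patch sampling, augmentation, thresholding."""

import numpy as np
import pytest

from organseg.core import AnnotationMask, ImageGrid, LabelMap, Modality, Volume
from organseg.preprocess import (
    AugmentationParams,
    NormalizationParams,
    augment,
    clamp_scale,
    resample_image,
    resample_labels_back,
    sample_patch,
    threshold_mask,
)

GRID = ImageGrid((16, 16, 16), (2.0, 2.0, 3.0))


def _vol(values, grid=GRID, modality=Modality.CT_HU):
    return Volume(grid, np.broadcast_to(np.asarray(values, float), grid.shape).copy(),
                  modality)


class TestClampScale:
    @pytest.mark.parametrize("hu,expected", [
        (800.0, 1.0), (2000.0, 1.0), (0.0, 0.0), (400.0, 0.5), (-2000.0, -1.0),
        (-800.0, -1.0),
    ])
    def test_fixed_points(self, hu, expected):
        out = clamp_scale(_vol(hu))
        assert np.all(out.values == expected)
        assert out.modality is Modality.NORMALIZED

    def test_range_and_monotonicity(self, rng):
        hu = rng.uniform(-3000, 3000, GRID.shape)
        out = clamp_scale(Volume(GRID, hu)).values
        assert out.min() >= -1.0 and out.max() <= 1.0
        flat_in, flat_out = hu.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= -1e-12)

    def test_idempotent_on_normalised_values(self, rng):
        hu = rng.uniform(-900, 900, GRID.shape)
        once = clamp_scale(Volume(GRID, hu))
        # renormalising the already-normalised values leaves them unchanged
        again = np.clip(once.values, -800, 800) / 800
        np.testing.assert_allclose(again, once.values / 800, atol=1e-12)
        np.testing.assert_array_equal(np.clip(once.values, -1, 1), once.values)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            NormalizationParams(clamp_low=100, clamp_high=-100)


class TestThresholdMask:
    def test_universal_range(self):
        vol = _vol(123.0)
        assert threshold_mask(vol, (-np.inf, np.inf)).all()

    def test_selects_exactly_bone(self):
        values = np.full(GRID.shape, -1000.0)
        values[4:8, 4:8, 4:8] = 700.0
        mask = threshold_mask(Volume(GRID, values), (200, 1500))
        np.testing.assert_array_equal(mask, values == 700.0)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_mask(_vol(0.0), (10, -10))

    def test_region_intersection(self):
        vol = _vol(100.0)
        region = np.zeros(GRID.shape, bool)
        region[0] = True
        mask = threshold_mask(vol, (0, 200), region=region)
        assert mask[0].all() and not mask[1:].any()


class TestResampling:
    def test_constant_volume_stays_constant(self):
        out = resample_image(_vol(60.0), (1.36, 1.36, 3.0))
        assert np.allclose(out.values, 60.0)
        assert out.grid.spacing == (1.36, 1.36, 3.0)

    def test_identity_spacing_unchanged(self):
        vol = _vol(0.0)
        vol.values[3, 4, 5] = 77.0
        out = resample_image(vol, GRID.spacing)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_linear_ramp_interpolates_exactly(self):
        grid = ImageGrid((4, 4, 8), (1.0, 1.0, 2.0))
        z = np.arange(8) * 2.0
        vol = Volume(grid, np.broadcast_to(z, (4, 4, 8)).copy())
        out = resample_image(vol, (1.0, 1.0, 1.0))
        # interior voxels of a linear ramp reproduce the ramp analytically
        zi = np.arange(out.grid.shape[2]) * 1.0
        expected = np.clip(zi, 0, z.max())
        np.testing.assert_allclose(out.values[2, 2], expected, atol=1e-9)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            resample_image(_vol(0.0), (0.0, 1, 1))

    def test_labels_same_grid_round_trip(self):
        labels = np.zeros(GRID.shape, np.int32)
        labels[2, 3, 4] = 9
        lm = LabelMap(GRID, labels)
        out = resample_labels_back(lm, GRID)
        np.testing.assert_array_equal(out.labels, labels)

    def test_labels_upsample_nearest_block(self):
        grid = ImageGrid((4, 4, 4), (2.0, 2.0, 2.0))
        labels = np.zeros(grid.shape, np.int32)
        labels[1, 1, 1] = 7
        fine = ImageGrid((8, 8, 8), (1.0, 1.0, 1.0))
        out = resample_labels_back(LabelMap(grid, labels), fine)
        assert (out.labels == 7).sum() == 8
        # nearest input index round(out*0.5) == 1 for fine indices {1,2,3} minus
        # those rounding to 2 -> block spans fine indices 1..2 per axis
        assert set(np.unique(out.labels)) == {0, 7}

    def test_labels_never_invent_values(self, rng):
        labels = rng.integers(0, 4, GRID.shape).astype(np.int32)
        fine = ImageGrid((23, 9, 31), (1.4, 3.6, 1.5))
        out = resample_labels_back(LabelMap(GRID, labels), fine)
        assert set(np.unique(out.labels)) <= set(np.unique(labels)) | {0}

    def test_disjoint_grids_rejected(self):
        far = ImageGrid((4, 4, 4), (1.0, 1.0, 1.0), origin=(1000.0, 0, 0))
        with pytest.raises(ValueError, match="disjoint"):
            resample_labels_back(LabelMap(GRID, np.zeros(GRID.shape, np.int32)), far)


class TestPatchSampling:
    def test_fully_annotated_mask_all_ones(self, organ_truth, rng):
        patch = sample_patch(organ_truth.ct, organ_truth.labels,
                             organ_truth.annotation, (20, 20, 20), rng)
        assert patch.validity.all()

    def test_missing_organ_gets_zero_weight(self, organ_truth, rng):
        present = sorted(organ_truth.annotation.annotated_labels)
        missing = present[0]
        ann = AnnotationMask(present[1:])
        for _ in range(10):
            patch = sample_patch(organ_truth.ct, organ_truth.labels, ann,
                                 (24, 24, 24), rng)
            assert not patch.validity[patch.labels == missing].any()
            assert patch.validity[patch.labels == 0].all()

    def test_fixed_seed_reproducible(self, organ_truth):
        a = sample_patch(organ_truth.ct, organ_truth.labels, organ_truth.annotation,
                         (16, 16, 16), np.random.default_rng(42))
        b = sample_patch(organ_truth.ct, organ_truth.labels, organ_truth.annotation,
                         (16, 16, 16), np.random.default_rng(42))
        assert a.origin_voxel == b.origin_voxel
        np.testing.assert_array_equal(a.image, b.image)

    def test_volume_smaller_than_patch_is_padded(self, rng):
        grid = ImageGrid((6, 6, 6), (1, 1, 1))
        vol = Volume(grid, np.zeros(grid.shape))
        lm = LabelMap(grid, np.zeros(grid.shape, np.int32))
        patch = sample_patch(vol, lm, AnnotationMask([]), (10, 10, 10), rng)
        assert patch.image.shape == (10, 10, 10)


class TestAugmentation:
    def test_zero_ranges_are_identity(self, organ_truth, rng):
        patch = sample_patch(organ_truth.ct, organ_truth.labels,
                             organ_truth.annotation, (16, 16, 16), rng)
        out = augment(patch, AugmentationParams(0.0, 0.0, 0.0), rng)
        np.testing.assert_array_equal(out.image, patch.image)
        np.testing.assert_array_equal(out.labels, patch.labels)

    def test_draws_stay_inside_stated_ranges(self):
        params = AugmentationParams()
        rng = np.random.default_rng(0)
        n = 10_000
        rot = rng.uniform(-params.rotation_rad, params.rotation_rad, n)
        shift = rng.uniform(-params.intensity_shift_hu, params.intensity_shift_hu, n)
        assert np.all(np.abs(rot) <= 0.15)
        assert np.all(np.abs(shift) <= 100.0)

    def test_shift_then_clamp_composition(self):
        vol = _vol(800.0)
        shifted = Volume(GRID, vol.values + 100.0)
        assert np.all(clamp_scale(shifted).values == 1.0)

    def test_intensity_shift_applies_to_image_only(self, organ_truth):
        rng = np.random.default_rng(1)
        patch = sample_patch(organ_truth.ct, organ_truth.labels,
                             organ_truth.annotation, (16, 16, 16), rng)
        out = augment(patch, AugmentationParams(0.0, 0.0, 100.0),
                      np.random.default_rng(2))
        delta = out.image - patch.image
        assert np.allclose(delta, delta.ravel()[0])
        assert abs(delta.ravel()[0]) <= 100.0
        np.testing.assert_array_equal(out.labels, patch.labels)

    def test_geometric_transform_moves_image_and_labels_together(self, organ_truth):
        rng = np.random.default_rng(3)
        patch = sample_patch(organ_truth.ct, organ_truth.labels,
                             organ_truth.annotation, (24, 24, 24), rng,
                             foreground_bias=1.0)
        out = augment(patch, AugmentationParams(0.15, 0.10, 0.0),
                      np.random.default_rng(4))
        # organ voxels (bright) should still coincide with nonzero labels
        organ = out.labels > 0
        if organ.sum() > 50:
            inside = out.image[organ].mean()
            outside = out.image[~organ].mean()
            assert inside > outside
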