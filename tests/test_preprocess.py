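"""Preprocessing chain: each operation against small exact oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepaseg import (
    ImageStack,
    PreprocessConfig,
    apply_cleaning_mask,
    crop_from_pad,
    downsample_axial,
    gaussian_blur,
    median_filter_slices,
    pad_mask_stack,
    pad_to_square,
    preprocess_stack,
    to_single_channel,
)


class TestDownsample:
    def test_halves_slices_and_doubles_z_spacing(self, rng):
        stack = ImageStack(voxels=rng.random((100, 8, 8)), spacing=(9.0, 9.0, 9.0))
        out = downsample_axial(stack, 2)
        assert out.shape[0] == 50
        assert out.spacing == (18.0, 9.0, 9.0)

    def test_stride_one_is_identity(self, rng):
        stack = ImageStack(voxels=rng.random((5, 4, 4)))
        out = downsample_axial(stack, 1)
        np.testing.assert_array_equal(out.voxels, stack.voxels)

    def test_index_arithmetic(self):
        # slice k is constant k -> output slice j is constant 2j
        voxels = np.stack([np.full((4, 4), k, dtype=float) for k in range(10)])
        out = downsample_axial(ImageStack(voxels=voxels), 2)
        for j in range(out.shape[0]):
            assert np.all(out.voxels[j] == 2 * j)

    def test_invalid_stride(self, rng):
        with pytest.raises(ValueError):
            downsample_axial(ImageStack(voxels=rng.random((4, 2, 2))), 0)


class TestMedian:
    def test_constant_slice_unchanged(self):
        stack = ImageStack(voxels=np.full((2, 8, 8), 0.4))
        out = median_filter_slices(stack, 2)
        np.testing.assert_array_equal(out.voxels, stack.voxels)

    def test_impulse_removed_at_radius_two(self):
        voxels = np.zeros((1, 9, 9))
        voxels[0, 4, 4] = 1.0
        out = median_filter_slices(ImageStack(voxels=voxels), 2)
        # a single bright pixel in a 5x5 window is below the median
        assert np.all(out.voxels == 0.0)

    def test_radius_zero_identity(self, rng):
        stack = ImageStack(voxels=rng.random((2, 5, 5)))
        out = median_filter_slices(stack, 0)
        np.testing.assert_array_equal(out.voxels, stack.voxels)


class TestSingleChannel:
    def test_uint8_normalized_by_255(self):
        voxels = np.array([[[0, 128, 255]]], dtype=np.uint8)
        out = to_single_channel(ImageStack(voxels=voxels))
        np.testing.assert_allclose(out.voxels, [[[0.0, 128 / 255, 1.0]]])

    def test_uint16_normalized_by_65535(self):
        voxels = np.array([[[0, 65535]]], dtype=np.uint16)
        out = to_single_channel(ImageStack(voxels=voxels))
        np.testing.assert_allclose(out.voxels, [[[0.0, 1.0]]])

    def test_float_passthrough(self, rng):
        voxels = rng.random((2, 3, 3)).astype(np.float32)
        out = to_single_channel(ImageStack(voxels=voxels))
        np.testing.assert_array_equal(out.voxels, voxels)

    def test_identical_channels_collapse(self, rng):
        one = rng.random((2, 3, 3))
        out = to_single_channel(np.stack([one] * 3, axis=-1))
        np.testing.assert_allclose(out.voxels, one, rtol=1e-6)

    def test_disagreeing_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            to_single_channel(rng.random((2, 3, 3, 3)))


class TestPad:
    def test_centering_offsets(self, rng):
        img = rng.random((300, 400))
        padded, (top, left) = pad_to_square(img, 512)
        assert padded.shape == (512, 512)
        assert (top, left) == (106, 56)
        np.testing.assert_array_equal(padded[106:406, 56:456], img)
        border = padded.copy()
        border[106:406, 56:456] = 0
        assert np.all(border == 0)

    def test_already_square_identity(self, rng):
        img = rng.random((512, 512))
        padded, offset = pad_to_square(img, 512)
        assert offset == (0, 0)
        np.testing.assert_array_equal(padded, img)

    def test_oversize_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            pad_to_square(rng.random((513, 100)), 512)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(h=st.integers(1, 64), w=st.integers(1, 64), target=st.integers(64, 96))
    def test_pad_then_crop_is_identity(self, h, w, target):
        img = np.random.default_rng(h * 97 + w).random((h, w))
        padded, offset = pad_to_square(img, target)
        np.testing.assert_array_equal(crop_from_pad(padded, offset, (h, w)), img)


class TestBlur:
    def test_constant_fixed_point(self):
        img = np.full((16, 16), 0.3)
        np.testing.assert_allclose(gaussian_blur(img, 5), img, atol=1e-6)

    def test_kernel_one_identity(self, rng):
        img = rng.random((8, 8))
        np.testing.assert_array_equal(gaussian_blur(img, 1), img)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            gaussian_blur(rng.random((8, 8)), 4)

    def test_impulse_response_sums_to_one(self):
        img = np.zeros((21, 21))
        img[10, 10] = 1.0
        out = gaussian_blur(img, 5)
        # interior impulse: the normalized kernel mass is preserved
        assert abs(out.sum() - 1.0) < 1e-6


class TestCleaning:
    def test_empty_mask_identity(self, rng):
        stack = ImageStack(voxels=rng.random((3, 4, 4)))
        out = apply_cleaning_mask(stack, np.zeros((3, 4, 4), dtype=np.uint8))
        np.testing.assert_array_equal(out.voxels, stack.voxels)

    def test_full_mask_zeroes_stack(self, rng):
        stack = ImageStack(voxels=rng.random((3, 4, 4)))
        out = apply_cleaning_mask(stack, np.ones((3, 4, 4), dtype=np.uint8))
        assert np.all(out.voxels == 0)

    def test_against_masked_assignment_oracle(self, small_phantom):
        _, ph = small_phantom
        out = apply_cleaning_mask(ph.stack, ph.confounder_mask)
        oracle = ph.stack.voxels.copy()
        oracle[ph.confounder_mask.astype(bool)] = 0
        np.testing.assert_array_equal(out.voxels, oracle)
        liver = ph.liver_mask.astype(bool)
        np.testing.assert_array_equal(out.voxels[liver], ph.stack.voxels[liver])

    def test_shape_mismatch_rejected(self, rng):
        stack = ImageStack(voxels=rng.random((3, 4, 4)))
        with pytest.raises(ValueError, match="shape"):
            apply_cleaning_mask(stack, np.zeros((2, 4, 4), dtype=np.uint8))


class TestPipeline:
    def test_shapes_and_mask_conservation(self, small_phantom):
        cfg, ph = small_phantom
        pcfg = PreprocessConfig(axial_keep_stride=2, target_size_px=64)
        pre, offset, orig = preprocess_stack(ph.stack, pcfg)
        assert pre.shape == (6, 64, 64)
        assert orig == (48, 48)
        assert pre.spacing[0] == ph.stack.spacing[0] * 2
        # geometric ops on the mask preserve its voxel count
        mask = ph.liver_mask[::2]
        padded, _ = pad_mask_stack(mask, 64)
        assert padded.sum() == mask.sum()

    def test_cleaning_inside_pipeline_removes_confounders(self, small_phantom):
        _, ph = small_phantom
        pcfg = PreprocessConfig(axial_keep_stride=2, target_size_px=64)
        pre_plain, _, _ = preprocess_stack(ph.stack, pcfg)
        pre_clean, _, _ = preprocess_stack(ph.stack, pcfg, cleaning=ph.confounder_mask)
        conf_p, _ = pad_mask_stack(ph.confounder_mask[::2], 64)
        conf = conf_p.astype(bool)
        assert np.all(pre_clean.voxels[conf] == 0)
        np.testing.assert_array_equal(pre_clean.voxels[~conf], pre_plain.voxels[~conf])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(blur_kernel_px=4)
        with pytest.raises(ValueError):
            PreprocessConfig(axial_keep_stride=0)

    def test_slice_image_export(self, tmp_path, small_phantom):
        from hepaseg import export_slice_images
        _, ph = small_phantom
        paths = export_slice_images(ph.stack, str(tmp_path / "png"), fmt="png")
        assert len(paths) == ph.stack.shape[0]
        import tifffile
        paths = export_slice_images(ph.stack, str(tmp_path / "tif"), fmt="tiff")
        img = tifffile.imread(paths[0])
        assert img.shape == ph.stack.shape[1:] and img.dtype == np.uint8
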