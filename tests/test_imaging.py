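"""Enhancement, thresholding and morphology against brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

from minml import (
    ClaheConfig,
    PreprocessConfig,
    clahe_enhance,
    dilate,
    erode,
    estimate_alpha,
    flatten,
    full_square,
    make_phantom,
    mean_filter,
    median_filter,
    phantom_region_masks,
    preprocess_pipeline,
    remove_skull,
    segment_hemorrhage,
    superimpose,
    unflatten,
    PhantomSpec,
)

from oracles import loop_dilate, loop_erode, loop_mean_filter, loop_median_filter


@pytest.fixture
def noisy_image(rng):
    return rng.integers(0, 256, size=(16, 16)).astype(np.uint8)


@pytest.fixture
def random_mask(rng):
    return (rng.random((12, 12)) < 0.4).astype(np.uint8) * 255


class TestClahe:
    def test_constant_image_stays_constant(self):
        img = np.full((32, 32), 77, dtype=np.uint8)
        out = clahe_enhance(img)
        assert np.unique(out).tolist() == [77]

    def test_output_stays_in_8bit_range(self, noisy_image):
        out = clahe_enhance(noisy_image, ClaheConfig(tile_grid=(2, 2)))
        assert out.dtype == np.uint8
        assert out.min() >= 0 and out.max() <= 255

    def test_low_contrast_ramp_gains_dynamic_range(self):
        ramp = np.tile(np.linspace(100, 140, 64).astype(np.uint8), (64, 1))
        out = clahe_enhance(ramp, ClaheConfig(tile_grid=(4, 4), clip_limit=0.05))
        assert int(out.max()) - int(out.min()) >= int(ramp.max()) - int(ramp.min())

    def test_tile_grid_must_fit(self):
        with pytest.raises(ValueError, match="tile grid"):
            clahe_enhance(np.zeros((8, 8), dtype=np.uint8) + 1,
                          ClaheConfig(tile_grid=(16, 16)))

    def test_rayleigh_distribution_unsupported(self, noisy_image):
        with pytest.raises(ValueError, match="uniform"):
            clahe_enhance(noisy_image, ClaheConfig(distribution="rayleigh"))


class TestSmoothingFilters:
    def test_constant_images_unchanged(self):
        img = np.full((7, 7), 7, dtype=np.uint8)
        assert np.array_equal(mean_filter(img, 3), img)
        assert np.array_equal(median_filter(img, 3), img)

    def test_mean_of_one_to_nine_center_is_five(self):
        img = np.arange(1, 10, dtype=np.uint8).reshape(3, 3)
        assert mean_filter(img, 3)[1, 1] == 5

    def test_impulse_spreads_to_rounded_average(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 255
        assert mean_filter(img, 3)[2, 2] == round(255 / 9)

    def test_median_removes_salt_impulse(self):
        img = np.full((5, 5), 10, dtype=np.uint8)
        img[2, 2] = 255
        assert median_filter(img, 3)[2, 2] == 10

    @pytest.mark.parametrize("size", [3, 5])
    def test_filters_match_sliding_window_oracles(self, noisy_image, size):
        np.testing.assert_array_equal(
            mean_filter(noisy_image, size), loop_mean_filter(noisy_image, size)
        )
        np.testing.assert_array_equal(
            median_filter(noisy_image, size), loop_median_filter(noisy_image, size)
        )

    @pytest.mark.parametrize("func", [mean_filter, median_filter])
    def test_even_window_rejected(self, func, noisy_image):
        with pytest.raises(ValueError, match="odd"):
            func(noisy_image, 4)


class TestThresholding:
    def test_alpha_255_changes_nothing(self, noisy_image):
        assert np.array_equal(remove_skull(noisy_image, 255), noisy_image)

    def test_alpha_0_zeroes_all_positive_pixels(self, noisy_image):
        out = remove_skull(noisy_image, 0)
        assert np.all(out[noisy_image > 0] == 0)
        assert np.all(out[noisy_image == 0] == noisy_image[noisy_image == 0])

    def test_skull_removal_matches_elementwise_oracle(self, rng):
        img = rng.integers(0, 256, size=(4, 4)).astype(np.uint8)
        out = remove_skull(img, 200)
        assert int((out == 0).sum() - (img == 0).sum()) == int((img > 200).sum()) - int(
            ((img > 200) & (img == 0)).sum()
        )
        for r in range(4):
            for c in range(4):
                expected = 0 if img[r, c] > 200 else img[r, c]
                assert out[r, c] == expected

    def test_output_never_exceeds_input(self, noisy_image):
        assert np.all(remove_skull(noisy_image, 130) <= noisy_image)

    def test_full_band_marks_everything(self, noisy_image):
        assert np.all(segment_hemorrhage(noisy_image, 0, 255) == 255)

    def test_degenerate_band_marks_exact_value(self):
        img = np.array([[10, 11], [9, 10]], dtype=np.uint8)
        mask = segment_hemorrhage(img, 10, 10)
        np.testing.assert_array_equal(mask, (img == 10) * 255)

    def test_band_matches_membership_oracle(self, noisy_image):
        mask = segment_hemorrhage(noisy_image, 130, 200)
        expected = ((noisy_image >= 130) & (noisy_image <= 200)) * 255
        np.testing.assert_array_equal(mask, expected.astype(np.uint8))

    def test_inverted_band_rejected(self, noisy_image):
        with pytest.raises(ValueError, match="alpha1"):
            segment_hemorrhage(noisy_image, 200, 130)

    def test_band_idempotent_when_band_contains_255_excludes_0(self, noisy_image):
        mask = segment_hemorrhage(noisy_image, 100, 255)
        np.testing.assert_array_equal(segment_hemorrhage(mask, 100, 255), mask)


class TestMorphology:
    def test_full_mask_erodes_to_center(self):
        mask = np.full((3, 3), 255, dtype=np.uint8)
        out = erode(mask, full_square(3))
        assert out[1, 1] == 255 and out.sum() == 255

    def test_empty_mask_fixed_point(self):
        empty = np.zeros((5, 5), dtype=np.uint8)
        assert np.array_equal(erode(empty, full_square(3)), empty)
        assert np.array_equal(dilate(empty, full_square(3)), empty)

    def test_single_pixel_dilates_to_block(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 255
        out = dilate(mask, full_square(3))
        np.testing.assert_array_equal(out[1:4, 1:4], 255)
        assert out.sum() == 9 * 255

    @pytest.mark.parametrize("se", [full_square(3), np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])])
    def test_matches_set_definition_oracles(self, random_mask, se):
        np.testing.assert_array_equal(erode(random_mask, se), loop_erode(random_mask, se))
        np.testing.assert_array_equal(dilate(random_mask, se), loop_dilate(random_mask, se))

    def test_asymmetric_se_matches_oracles(self, random_mask):
        se = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0]])  # origin set, asymmetric
        np.testing.assert_array_equal(erode(random_mask, se), loop_erode(random_mask, se))
        np.testing.assert_array_equal(dilate(random_mask, se), loop_dilate(random_mask, se))

    def test_agrees_with_scipy_in_the_interior(self, random_mask):
        se = full_square(3)
        ours = dilate(random_mask, se) > 0
        ref = ndimage.binary_dilation(random_mask > 0, structure=se)
        np.testing.assert_array_equal(ours, ref)

    def test_duality_with_foreground_padding(self, random_mask):
        se = full_square(3)
        complement = 255 - random_mask
        np.testing.assert_array_equal(
            dilate(random_mask, se), 255 - erode(complement, se, pad=255)
        )

    def test_erosion_anti_extensive_dilation_extensive(self, random_mask):
        se = full_square(3)
        eroded = erode(random_mask, se)
        dilated = dilate(random_mask, se)
        assert np.all(eroded <= random_mask)
        assert np.all(random_mask <= dilated)

    def test_even_se_rejected(self, random_mask):
        with pytest.raises(ValueError, match="odd"):
            erode(random_mask, np.ones((2, 2)))


class TestSuperimposeFlatten:
    def test_empty_mask_keeps_base(self, noisy_image):
        empty = np.zeros_like(noisy_image)
        assert np.array_equal(superimpose(noisy_image, empty), noisy_image)

    def test_full_mask_whites_out(self, noisy_image):
        full = np.full_like(noisy_image, 255)
        assert np.all(superimpose(noisy_image, full) == 255)

    def test_elementwise_select(self):
        base = np.array([[10, 20], [30, 40]], dtype=np.uint8)
        mask = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        np.testing.assert_array_equal(
            superimpose(base, mask), np.array([[10, 255], [255, 40]])
        )

    def test_shape_mismatch_rejected(self, noisy_image):
        with pytest.raises(ValueError, match="shape"):
            superimpose(noisy_image, np.zeros((2, 2), dtype=np.uint8))

    def test_flatten_row_major_and_round_trip(self, noisy_image):
        assert flatten([[1, 2], [3, 4]]).tolist() == [1, 2, 3, 4]
        assert np.array_equal(unflatten(flatten(noisy_image), noisy_image.shape), noisy_image)

    def test_flatten_size_arithmetic(self):
        assert flatten(np.zeros((128, 128), dtype=np.uint8)).size == 16384


class TestEstimateAlpha:
    def test_constant_image(self):
        assert estimate_alpha([np.full((4, 4), 50, dtype=np.uint8)]) == 50.0

    def test_average_of_image_means(self):
        imgs = [np.zeros((4, 4), dtype=np.uint8), np.full((2, 2), 100, dtype=np.uint8)]
        assert estimate_alpha(imgs) == 50.0

    def test_matches_double_mean_oracle(self, rng):
        imgs = [rng.integers(0, 256, size=(6, 6)).astype(np.uint8) for _ in range(4)]
        expected = sum(float(np.mean(i)) for i in imgs) / 4
        assert estimate_alpha(imgs) == pytest.approx(expected)

    def test_region_masks_restrict_the_mean(self, rng):
        img = rng.integers(0, 256, size=(6, 6)).astype(np.uint8)
        mask = np.zeros((6, 6), dtype=bool)
        mask[:2] = True
        assert estimate_alpha([img], [mask]) == pytest.approx(float(img[:2].mean()))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            estimate_alpha([])


class TestPipeline:
    @pytest.fixture
    def matched_config(self):
        # band matched to the phantom blob intensities, enhancement off so
        # the raw tissue bands survive to the segmentation stage
        return PreprocessConfig(
            clahe={"enabled": False},
            noise_filter={"kind": "median", "size": 3},
            alpha=210.0,
            alpha1=140.0,
            alpha2=210.0,
        )

    def test_mask_overlaps_planted_blob(self, matched_config):
        img, blob = make_phantom(PhantomSpec(seed=5, noise_sigma=0.0))
        result = preprocess_pipeline(img, matched_config)
        planted = blob > 0
        recovered = result.mask > 0
        assert (recovered & planted).sum() / planted.sum() > 0.8

    def test_band_alone_recovers_most_blob_pixels(self):
        img, blob = make_phantom(PhantomSpec(seed=6, noise_sigma=0.0))
        mask = segment_hemorrhage(img, 150, 200)
        planted = blob > 0
        assert ((mask > 0) & planted).sum() / planted.sum() >= 0.9

    def test_skull_removal_zeroes_ring_preserves_brain(self):
        spec = PhantomSpec(seed=7, noise_sigma=0.0, blob=False)
        img, _ = make_phantom(spec)
        regions = phantom_region_masks(spec)
        out = remove_skull(img, 210)
        assert np.all(out[regions["skull"]] == 0)
        np.testing.assert_array_equal(out[regions["brain"]], img[regions["brain"]])

    def test_no_blob_with_out_of_band_limits_gives_empty_mask(self, matched_config):
        img, _ = make_phantom(PhantomSpec(seed=8, blob=False, noise_sigma=0.0))
        result = preprocess_pipeline(img, matched_config)
        assert not (result.mask > 0).any()
        np.testing.assert_array_equal(result.superimposed, result.skull_removed)

    def test_all_zero_image_stays_zero(self, matched_config):
        zero = np.zeros((32, 32), dtype=np.uint8)
        result = preprocess_pipeline(zero, matched_config)
        for stage in result.stages().values():
            assert not stage.any()

    def test_bit_identical_rerun(self, matched_config):
        img, _ = make_phantom(PhantomSpec(seed=9))
        a = preprocess_pipeline(img, matched_config)
        b = preprocess_pipeline(img, matched_config)
        for name in a.stages():
            np.testing.assert_array_equal(a.stages()[name], b.stages()[name])

    def test_config_json_round_trip(self, tmp_path, matched_config):
        path = tmp_path / "cfg.json"
        matched_config.save(path)
        loaded = PreprocessConfig.load(path)
        assert loaded.to_dict() == matched_config.to_dict()
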