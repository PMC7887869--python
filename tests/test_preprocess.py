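import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from earmatch import (
    ConfigError,
    CropROI,
    EarImage,
    InvalidImageError,
    InvalidROIError,
    PipelineConfig,
    crop,
    equalize_histogram,
    preprocess,
    resize_to_width,
    to_grayscale,
)


class TestToGrayscale:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 0, 0), 76),  # 0.299*255 = 76.245, rounded half up
            ((0, 255, 0), 150),  # 0.587*255 = 149.685
            ((0, 0, 255), 29),  # 0.114*255 = 29.07
            ((100, 100, 100), 100),  # equal channels: luma weights sum to 1
            ((255, 255, 255), 255),
        ],
    )
    def test_bt601_luma_single_pixel(self, rgb, expected):
        img = to_grayscale(np.array([[rgb]], dtype=np.uint8))
        assert img.pixels[0, 0] == expected

    def test_grayscale_passthrough(self, rng):
        px = rng.integers(0, 256, size=(20, 30), dtype=np.uint8)
        assert np.array_equal(to_grayscale(px).pixels, px)

    def test_metadata_attached(self):
        img = to_grayscale(np.zeros((4, 4), np.uint8), subject_id="s1", gender="F")
        assert (img.subject_id, img.gender) == ("s1", "F")

    @pytest.mark.parametrize("bad", [np.empty((0, 0)), np.zeros((3, 3, 4), np.uint8)])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(InvalidImageError):
            to_grayscale(bad)


class TestCrop:
    def test_full_frame_is_identity(self, rng):
        img = EarImage(rng.integers(0, 256, (10, 10), dtype=np.uint8))
        out = crop(img, CropROI(0, 0, 10, 10))
        assert np.array_equal(out.pixels, img.pixels)

    def test_half_open_arithmetic(self):
        img = EarImage(np.zeros((1000, 2000), np.uint8))
        out = crop(img, CropROI(500, 100, 1700, 900))
        assert (out.width, out.height) == (1200, 800)

    def test_pixels_copied_verbatim(self, rng):
        px = rng.integers(0, 256, (8, 9), dtype=np.uint8)
        out = crop(EarImage(px), CropROI(2, 1, 7, 5))
        assert np.array_equal(out.pixels, px[1:5, 2:7])

    def test_out_of_bounds_rejected(self):
        img = EarImage(np.zeros((10, 10), np.uint8))
        with pytest.raises(InvalidROIError):
            crop(img, CropROI(5, 5, 15, 8))

    @pytest.mark.parametrize("roi", [(3, 3, 3, 8), (4, 2, 2, 6), (-1, 0, 5, 5)])
    def test_degenerate_roi_rejected(self, roi):
        with pytest.raises(InvalidROIError):
            CropROI(*roi)

    def test_metadata_preserved(self):
        img = EarImage(np.zeros((10, 10), np.uint8), subject_id="x", capture_index=2)
        out = crop(img, CropROI(0, 0, 5, 5))
        assert (out.subject_id, out.capture_index) == ("x", 2)


class TestResize:
    @pytest.mark.parametrize(
        "in_size, width, out_size",
        [
            ((2000, 1000), 150, (150, 75)),  # the canonical ~10x shrink
            ((300, 100), 150, (150, 50)),
            ((100, 40), 200, (200, 80)),  # enlargement
            ((150, 2), 75, (75, 1)),  # height floor of 1
        ],
    )
    def test_dimensions(self, in_size, width, out_size, rng):
        w, h = in_size
        img = EarImage(rng.integers(0, 256, (h, w), dtype=np.uint8))
        out = resize_to_width(img, width)
        assert (out.width, out.height) == out_size

    def test_noop_at_target_width(self, rng):
        img = EarImage(rng.integers(0, 256, (80, 150), dtype=np.uint8))
        out = resize_to_width(img, 150)
        assert np.array_equal(out.pixels, img.pixels)

    def test_aspect_ratio_within_rounding(self, rng):
        img = EarImage(rng.integers(0, 256, (777, 1234), dtype=np.uint8))
        out = resize_to_width(img, 150)
        exact = 777 * 150 / 1234
        assert abs(out.height - exact) <= 0.5

    def test_box_shrink_averages(self):
        # 2x2 blocks of a checkerboard average to the mid gray under area resampling
        px = np.zeros((4, 4), np.uint8)
        px[::2, 1::2] = 255
        px[1::2, ::2] = 255
        out = resize_to_width(EarImage(px), 2)
        assert np.all(np.abs(out.pixels.astype(int) - 128) <= 1)


class TestHistogramEqualization:
    def test_two_pixel_worked_example(self):
        # N=2, cdf_min=1: 10 -> 0, 20 -> 255
        out = equalize_histogram(EarImage(np.array([[10, 20]], np.uint8)))
        assert out.pixels.tolist() == [[0, 255]]

    def test_four_pixel_cdf_formula(self):
        # {0,0,128,255}: cdf = 2,3,4; cdf_min=2, N=4
        # v' = round((cdf-2)/(4-2)*255) -> 0, 128 (127.5 up), 255
        out = equalize_histogram(EarImage(np.array([[0, 0, 128, 255]], np.uint8)))
        assert out.pixels.tolist() == [[0, 0, 128, 255]]

    def test_constant_image_is_identity(self):
        img = EarImage(np.full((5, 5), 42, np.uint8))
        assert np.array_equal(equalize_histogram(img).pixels, img.pixels)

    def test_output_spans_full_range(self, rng):
        # a narrow band of intensities is stretched to [0, 255]
        px = rng.integers(100, 120, size=(50, 50), dtype=np.uint8)
        out = equalize_histogram(EarImage(px))
        assert out.pixels.min() == 0 and out.pixels.max() == 255

    @given(
        hnp.arrays(np.uint8, hnp.array_shapes(min_dims=2, max_dims=2,
                                              min_side=2, max_side=32))
    )
    def test_mapping_monotone_over_all_levels(self, px):
        # embed all 256 levels so the induced intensity map is fully observable
        full = np.concatenate([px.ravel(), np.arange(256, dtype=np.uint8)])
        img = EarImage(full.reshape(1, -1))
        out = equalize_histogram(img).pixels.ravel()
        lut = np.zeros(256, int)
        for v, o in zip(img.pixels.ravel(), out):
            lut[v] = o
        assert np.all(np.diff(lut) >= 0)

    def test_matches_independent_reference(self, rng):
        # cross-check against scikit-image's integer equalization (CLAHE-free)
        from skimage import exposure

        px = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
        ours = equalize_histogram(EarImage(px)).pixels
        ref = exposure.equalize_hist(px, nbins=256) * 255
        # formulas differ by the cdf_min shift; agreement within 1 level after
        # rescaling the reference by the same shift
        n = px.size
        hist = np.bincount(px.ravel(), minlength=256)
        cdf_min = int(np.cumsum(hist)[np.nonzero(hist)[0][0]])
        adj = (ref * n / 255 - cdf_min) / (n - cdf_min) * 255
        assert np.max(np.abs(ours.astype(float) - adj)) <= 1.0


class TestPipeline:
    def test_all_stages_off_equals_grayscale(self, rng):
        raw = rng.integers(0, 256, size=(30, 40, 3), dtype=np.uint8)
        config = PipelineConfig(use_crop=False, use_resize=False, use_hist_eq=False,
                                use_concatenation=False, use_gender_filter=False)
        out = preprocess(raw, config)
        assert np.array_equal(out.pixels, to_grayscale(raw).pixels)

    def test_crop_then_resize_composition(self, rng):
        raw = rng.integers(0, 256, size=(1000, 2000), dtype=np.uint8)
        config = PipelineConfig(use_hist_eq=False)
        out = preprocess(raw, config, CropROI(100, 100, 1600, 900))
        assert out.width == 150

    def test_resize_he_without_crop_is_legal(self, rng):
        raw = rng.integers(0, 256, size=(400, 600), dtype=np.uint8)
        config = PipelineConfig(use_crop=False)
        out = preprocess(raw, config)
        assert out.width == 150

    def test_missing_roi_with_crop_errors(self, rng):
        raw = rng.integers(0, 256, size=(40, 40), dtype=np.uint8)
        with pytest.raises(ConfigError):
            preprocess(raw, PipelineConfig())

    def test_deterministic(self, rng):
        raw = rng.integers(0, 256, size=(300, 500, 3), dtype=np.uint8)
        config = PipelineConfig()
        roi = CropROI(50, 40, 450, 280)
        a = preprocess(raw, config, roi)
        b = preprocess(raw, config, roi)
        assert np.array_equal(a.pixels, b.pixels)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            PipelineConfig(target_width=4)
        with pytest.raises(ConfigError):
            PipelineConfig(top_k=0)

    def test_fingerprint_separates_regimes(self):
        a = PipelineConfig().preprocessing_fingerprint("b1")
        b = PipelineConfig(use_hist_eq=False).preprocessing_fingerprint("b1")
        c = PipelineConfig().preprocessing_fingerprint("b2")
        assert len({a, b, c}) == 3
        # concatenation/filter flags do not touch descriptors
        d = PipelineConfig(use_concatenation=False).preprocessing_fingerprint("b1")
        assert a == d
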