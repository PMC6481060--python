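import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from brightseg import (
    BinaryMask,
    Image,
    MorphOptions,
    binary_close,
    binary_open,
    count_dilate,
    count_erode,
    make_circular_kernel,
    maximum_filter,
)

from _oracles import (
    dilate_oracle,
    erode_oracle,
    kernel_offsets_oracle,
    maximum_filter_oracle,
)

bool_masks = hnp.arrays(dtype=bool, shape=(9, 9))


class TestCircularKernel:
    @pytest.mark.parametrize("radius", [0.5, 1, 1.25, 1.67, 2.5, 5])
    def test_matches_enumeration_oracle(self, radius):
        kernel = make_circular_kernel(radius)
        assert set(kernel.offsets) == kernel_offsets_oracle(radius)

    def test_radius_1_25_is_full_3x3(self):
        # 1.25^2 + 1 = 2.5625 >= 2, so the diagonals are included
        assert len(make_circular_kernel(1.25).offsets) == 9

    def test_contains_origin_and_is_symmetric(self):
        for radius in (0.7, 1.0, 2.5, 5.0):
            offsets = make_circular_kernel(radius).offsets
            assert (0, 0) in offsets
            assert all((-dy, -dx) in offsets for dy, dx in offsets)

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            make_circular_kernel(0)

    def test_footprint_shape_and_content(self):
        kernel = make_circular_kernel(5)
        fp = kernel.footprint
        assert fp.shape == (11, 11)
        assert fp.sum() == len(kernel.offsets)


class TestMaximumFilter:
    def test_constant_image_unchanged(self):
        img = Image(pixels=np.full((10, 10), 9, dtype=np.int64), bit_depth=8)
        np.testing.assert_array_equal(maximum_filter(img, 5).pixels, img.pixels)

    def test_single_pixel_expands_to_kernel_footprint(self):
        arr = np.zeros((21, 21), dtype=np.int64)
        arr[10, 10] = 255
        out = maximum_filter(Image(pixels=arr, bit_depth=8), 5).pixels
        expected = {(10 + dy, 10 + dx) for dy, dx in make_circular_kernel(5).offsets}
        assert set(zip(*np.where(out == 255))) == expected

    @pytest.mark.parametrize("radius", [1, 1.25, 1.67, 2.5, 5])
    def test_matches_shift_and_max_oracle(self, rng, radius):
        for _ in range(3):
            arr = rng.integers(0, 256, (32, 32)).astype(np.int64)
            out = maximum_filter(arr, radius)
            np.testing.assert_array_equal(out, maximum_filter_oracle(arr, radius))

    @settings(deadline=None, max_examples=30)
    @given(
        hnp.arrays(dtype=np.int64, shape=(12, 12), elements=st.integers(0, 255)),
        st.sampled_from([1, 1.67, 2.5]),
    )
    def test_output_dominates_input(self, arr, radius):
        assert np.all(maximum_filter(arr, radius) >= arr)

    def test_binary_input_equals_kernel_dilation(self, rng):
        mask = rng.random((20, 20)) > 0.8
        out = maximum_filter(mask, 2.5)
        # count=1 dilation over the circular kernel: foreground wherever the
        # kernel centred there touches any foreground pixel
        expected = maximum_filter_oracle(mask.astype(np.int64), 2.5).astype(bool)
        np.testing.assert_array_equal(out, expected)


class TestCountMorphology:
    def test_empty_mask_fixed_point(self):
        empty = np.zeros((8, 8), dtype=bool)
        opts = MorphOptions(iterations=3, count=3, pad=True)
        for op in (count_erode, count_dilate, binary_close, binary_open):
            assert not op(empty, opts).any()

    def test_full_mask_survives_padded_erosion(self):
        full = BinaryMask(pixels=np.ones((8, 8), dtype=bool))
        out = count_erode(full, MorphOptions(iterations=10, count=3, pad=True))
        assert out.pixels.all()

    def test_full_mask_shrinks_without_pad(self):
        full = np.ones((8, 8), dtype=bool)
        out = count_erode(full, MorphOptions(iterations=1, count=3, pad=False))
        # corners have 5 out-of-image (background) neighbours >= 3: removed
        assert not out[0, 0] and out[4, 4]

    def test_random_masks_match_neighbor_count_oracle(self, rng):
        for count in (1, 3, 8):
            for pad in (False, True):
                mask = rng.random((9, 9)) > 0.5
                opts = MorphOptions(iterations=1, count=count, pad=pad)
                np.testing.assert_array_equal(
                    count_erode(mask, opts), erode_oracle(mask, count, pad)
                )
                np.testing.assert_array_equal(
                    count_dilate(mask, opts), dilate_oracle(mask, count)
                )

    def test_single_pixel_dilates_to_3x3_block(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        out = count_dilate(mask, MorphOptions(iterations=1, count=1))
        np.testing.assert_array_equal(out, dilate_oracle(mask, 1))
        assert out[1:4, 1:4].all() and out.sum() == 9

    def test_dilation_is_extensive_and_erosion_antiextensive(self, rng):
        mask = rng.random((12, 12)) > 0.5
        opts = MorphOptions(iterations=2, count=3)
        assert np.all(mask <= count_dilate(mask, opts))
        assert np.all(count_erode(mask, opts) <= mask)

    @settings(deadline=None, max_examples=40)
    @given(bool_masks, bool_masks, st.sampled_from([1, 3, 8]))
    def test_monotonicity_in_the_mask(self, a, b, count):
        lower = a & b  # lower <= a by construction
        opts = MorphOptions(iterations=1, count=count)
        assert np.all(count_erode(lower, opts) <= count_erode(a, opts))
        assert np.all(count_dilate(lower, opts) <= count_dilate(a, opts))

    @settings(deadline=None, max_examples=40)
    @given(hnp.arrays(dtype=bool, shape=(32, 32)), st.sampled_from([1, 3, 8]))
    def test_erode_dilate_duality_on_interior(self, mask, count):
        # away from borders erosion of the mask is the complement of dilating
        # the complement; at borders the two out-of-image conventions differ
        opts = MorphOptions(iterations=1, count=count, pad=False)
        left = count_erode(mask, opts)
        right = ~count_dilate(~mask, opts)
        np.testing.assert_array_equal(left[1:-1, 1:-1], right[1:-1, 1:-1])

    def test_invalid_options_rejected(self):
        with pytest.raises(ValueError):
            MorphOptions(iterations=0)
        with pytest.raises(ValueError):
            MorphOptions(count=0)
        with pytest.raises(ValueError):
            MorphOptions(count=9)


class TestOpenClose:
    def test_close_fills_small_hole(self):
        # frame large enough that 10 dilation passes stay clear of the border
        yy, xx = np.indices((80, 80))
        disc = (yy - 40) ** 2 + (xx - 40) ** 2 <= 14**2
        hole = (yy - 40) ** 2 + (xx - 40) ** 2 <= 1  # 2 px-scale hole
        mask = disc & ~hole
        out = np.asarray(binary_close(mask, MorphOptions(iterations=10, count=3, pad=True)))
        assert out[40, 40]  # hole filled
        # outer boundary within 1 px of the oracle composition
        expected = mask
        for _ in range(10):
            expected = dilate_oracle(expected, 3)
        for _ in range(10):
            expected = erode_oracle(expected, 3, True)
        np.testing.assert_array_equal(out, expected)
        outer = (yy - 40) ** 2 + (xx - 40) ** 2 <= 15.5**2
        assert not (out & ~outer).any()

    def test_open_removes_isolated_speck(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:7, 5:7] = True  # 2x2 speck: every pixel has >=5 bg neighbours
        out = binary_open(mask, MorphOptions(iterations=1, count=3))
        assert not out.any()

    def test_open_preserves_large_blob(self):
        mask = np.zeros((60, 60), dtype=bool)
        yy, xx = np.indices(mask.shape)
        blob = (yy - 30) ** 2 + (xx - 30) ** 2 <= 20**2
        out = binary_open(blob, MorphOptions(iterations=2, count=3))
        # bounded area change: interior survives, boundary moves <= 2 px in
        inner = (yy - 30) ** 2 + (xx - 30) ** 2 <= 18**2
        assert (np.asarray(out) & inner).sum() == inner.sum()

    def test_close_open_match_oracle_composition(self, rng):
        mask = rng.random((15, 15)) > 0.5
        opts = MorphOptions(iterations=2, count=3, pad=True)
        expected = mask
        for _ in range(2):
            expected = dilate_oracle(expected, 3)
        for _ in range(2):
            expected = erode_oracle(expected, 3, True)
        np.testing.assert_array_equal(binary_close(mask, opts), expected)

        expected = mask
        for _ in range(2):
            expected = erode_oracle(expected, 3, True)
        for _ in range(2):
            expected = dilate_oracle(expected, 3)
        np.testing.assert_array_equal(binary_open(mask, opts), expected)

    def test_binary_mask_wrapper_round_trip(self, rng):
        mask = BinaryMask(pixels=rng.random((10, 10)) > 0.5)
        out = binary_close(mask, MorphOptions(iterations=1, count=3))
        assert isinstance(out, BinaryMask)
        assert out.shape == mask.shape
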