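"""ROI masking against a brute-force morphology oracle, resizing,
normalization and CLAHE behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_closure, global_equalize, nearest_resize
from vesselgan.preprocess import (
    BinaryMask,
    PreprocessConfig,
    SliceImage,
    apply_mask,
    clahe_enhance,
    denormalize,
    make_roi_mask,
    morphological_closure,
    normalize_for_network,
    resize_slice,
)

RAW = (0.0, 255.0)


class TestRoiMask:
    def test_all_zero_image_gives_empty_mask(self):
        mask = make_roi_mask(SliceImage(np.zeros((16, 16)), RAW))
        assert mask.pixels.sum() == 0

    def test_saturated_image_gives_full_mask(self):
        mask = make_roi_mask(SliceImage(np.full((16, 16), 255.0), RAW))
        assert mask.pixels.all()

    def test_closure_fills_central_hole(self):
        px = np.full((21, 21), 200.0)
        px[9:12, 9:12] = 0.0
        mask = make_roi_mask(SliceImage(px, RAW), PreprocessConfig(closure_kernel=9))
        assert mask.pixels.all()
        # independent route: brute-force dilate-then-erode
        assert brute_force_closure(px >= 10.0, 9).all()

    def test_pixels_at_exactly_threshold_are_kept(self):
        px = np.full((12, 12), 10.0)
        mask = make_roi_mask(SliceImage(px, RAW))
        assert mask.pixels.all()

    def test_threshold_outside_declared_range_warns(self):
        img = SliceImage(np.random.default_rng(0).random((8, 8)), (0.0, 1.0))
        with pytest.warns(UserWarning, match="threshold"):
            make_roi_mask(img, PreprocessConfig(threshold=10.0))

    @pytest.mark.parametrize("k", [3, 5, 9])
    def test_closure_matches_brute_force_oracle(self, rng, k):
        for _ in range(25):
            binary = rng.random((rng.integers(8, 15), rng.integers(8, 15))) > 0.6
            ours = morphological_closure(binary, np.ones((k, k), bool))
            assert np.array_equal(ours, brute_force_closure(binary, k))

    def test_remasking_keeps_all_surviving_positives(self, rng):
        cfg = PreprocessConfig()
        for seed in range(10):
            px = np.random.default_rng(seed).random((20, 20)) * 255.0
            img = SliceImage(px, RAW)
            m1 = make_roi_mask(img, cfg)
            masked = apply_mask(img, m1)
            m2 = make_roi_mask(masked, cfg)
            surviving = (masked.pixels >= cfg.threshold) & m1.pixels.astype(bool)
            assert np.all(m2.pixels.astype(bool)[surviving])


class TestApplyMask:
    def test_identity_and_annihilator_masks(self, rng):
        img = SliceImage(rng.random((8, 8)) * 255, RAW)
        ones = BinaryMask(np.ones((8, 8), np.uint8))
        zeros = BinaryMask(np.zeros((8, 8), np.uint8))
        assert np.array_equal(apply_mask(img, ones).pixels, img.pixels)
        assert apply_mask(img, zeros).pixels.sum() == 0

    def test_elementwise_product(self):
        img = SliceImage(np.array([[5.0, 7.0], [2.0, 9.0]]), RAW)
        mask = BinaryMask(np.array([[1, 0], [0, 1]], np.uint8))
        assert np.array_equal(apply_mask(img, mask).pixels, [[5.0, 0.0], [0.0, 9.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_mask(SliceImage(np.zeros((4, 4))), BinaryMask(np.zeros((5, 5), np.uint8)))


class TestResize:
    def test_constant_image_stays_constant(self):
        out = resize_slice(SliceImage(np.full((10, 10), 0.4)), 16)
        assert np.allclose(out.pixels, 0.4, atol=1e-6)
        assert out.shape == (16, 16)

    def test_mask_resize_stays_binary(self, rng):
        mask = BinaryMask((rng.random((13, 13)) > 0.5).astype(np.uint8))
        out = resize_slice(mask, 7)
        assert set(np.unique(out.pixels)) <= {0, 1}

    def test_nearest_uses_top_left_sample_convention(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        out = resize_slice(BinaryMask(board.astype(np.uint8)), 2)
        assert np.array_equal(out.pixels, nearest_resize(board, 2))

    @pytest.mark.parametrize("target", [3, 5, 8])
    def test_nearest_matches_index_mapping_oracle(self, rng, target):
        px = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        out = resize_slice(BinaryMask(px), target)
        assert np.array_equal(out.pixels, nearest_resize(px, target))


class TestClahe:
    def test_constant_image_unchanged(self):
        img = SliceImage(np.full((32, 32), 0.3))
        assert np.array_equal(clahe_enhance(img).pixels, img.pixels)

    def test_cdf_dominates_at_low_end_for_low_contrast_ramp(self):
        ramp = np.tile(np.linspace(0.4, 0.6, 64), (64, 1))
        out = clahe_enhance(SliceImage(ramp), PreprocessConfig(clahe_clip=0.05)).pixels
        grid = np.linspace(0.05, 0.45, 20)
        cdf_in = [(ramp <= g).mean() for g in grid]
        cdf_out = [(out <= g).mean() for g in grid]
        assert all(o >= i for o, i in zip(cdf_out, cdf_in))
        assert sum(cdf_out) > sum(cdf_in)

    def test_unclipped_single_tile_approximates_global_equalization(self, rng):
        px = rng.beta(2, 5, (64, 64))
        cfg = PreprocessConfig(clahe_clip=1.0, clahe_tiles=1)
        ours = clahe_enhance(SliceImage(px), cfg).pixels
        ref = global_equalize(px)
        assert np.corrcoef(ours.ravel(), ref.ravel())[0, 1] > 0.99
        assert np.mean(np.abs(ours - ref)) < 0.05


class TestNormalize:
    def test_endpoints_and_midpoint(self):
        img = SliceImage(np.array([[0.0, 127.5, 255.0]] * 2), RAW)
        out = normalize_for_network(img, (-1.0, 1.0))
        assert np.allclose(out.pixels[0], [-1.0, 0.0, 1.0], atol=1e-6)

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(0.0, 255.0), st.floats(-2.0, -0.5), st.floats(0.5, 2.0))
    def test_round_trip_is_identity(self, value, lo, hi):
        img = SliceImage(np.full((3, 3), value), RAW)
        back = denormalize(normalize_for_network(img, (lo, hi)), RAW)
        assert np.allclose(back.pixels, value, atol=1e-3)

    def test_degenerate_declared_range_rejected(self):
        img = SliceImage(np.zeros((2, 2)), (0.0, 1.0))
        img.value_range = (5.0, 5.0)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_for_network(img)
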