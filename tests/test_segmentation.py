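import numpy as np
import pytest

from pulsecam.errors import ConfigurationError, ShapeMismatchError
from pulsecam.preprocess import RegionGrid
from pulsecam.segmentation import (
    CAUCASIAN_THRESHOLDS,
    ChannelThresholds,
    apply_mask,
    binarize_channel,
    combine_masks,
    otsu_thresholds,
    region_mean_brightness,
    skin_mask,
)
from pulsecam.video_io import FrameSequence


def _seq_from_colors(colors, n_frames=1):
    """A 1×K×3×I sequence holding the given (R, G, B) colours."""
    arr = np.array(colors, np.float32).reshape(1, -1, 3)
    frames = np.repeat(arr[:, :, :, None], n_frames, axis=3)
    return FrameSequence(frames, 30.0)


class TestThresholds:
    def test_published_skin_ranges_are_the_default(self):
        assert CAUCASIAN_THRESHOLDS.r == (0.59, 0.78)
        assert CAUCASIAN_THRESHOLDS.g == (0.48, 0.63)
        assert CAUCASIAN_THRESHOLDS.b == (0.48, 0.63)

    def test_invalid_order_rejected(self):
        with pytest.raises(ConfigurationError):
            ChannelThresholds(r=(0.8, 0.6))


class TestBinarizeChannel:
    def test_red_inside_range_is_skin(self):
        seq = _seq_from_colors([(0.60, 0.5, 0.5)])
        assert binarize_channel(seq, "R", 0.59, 0.78)[0, 0, 0]

    def test_lower_threshold_is_strict(self):
        # a value exactly at p1 is background, exactly at p2 is skin
        seq = _seq_from_colors([(0.59, 0.5, 0.5), (0.78, 0.5, 0.5)])
        mask = binarize_channel(seq, "R", 0.59, 0.78)
        assert not mask[0, 0, 0]
        assert mask[0, 1, 0]

    def test_uniform_gray_has_no_red_skin(self):
        seq = _seq_from_colors([(0.5, 0.5, 0.5)] * 4)
        assert binarize_channel(seq, "R", 0.59, 0.78).sum() == 0

    def test_equal_thresholds_rejected(self):
        seq = _seq_from_colors([(0.5, 0.5, 0.5)])
        with pytest.raises(ConfigurationError):
            binarize_channel(seq, "R", 0.6, 0.6)


class TestCombineMasks:
    def test_skin_colour_passes_all_three_ranges(self):
        seq = _seq_from_colors([(0.65, 0.55, 0.50)])
        assert skin_mask(seq)[0, 0, 0]

    def test_green_outside_range_fails(self):
        seq = _seq_from_colors([(0.65, 0.40, 0.50)])
        assert not skin_mask(seq)[0, 0, 0]

    def test_and_identity(self, rng):
        ones = np.ones((5, 5, 2), bool)
        m = rng.random((5, 5, 2)) < 0.5
        assert np.array_equal(combine_masks(m, ones, ones), m)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            combine_masks(
                np.ones((2, 2, 1), bool),
                np.ones((2, 3, 1), bool),
                np.ones((2, 2, 1), bool),
            )

    def test_equals_brute_force_triple_range_check(self, rng):
        # oracle equivalence on random frames, pixel by pixel
        frames = rng.random((12, 14, 3, 4)).astype(np.float32)
        seq = FrameSequence(frames, 30.0)
        mask = skin_mask(seq)
        t = CAUCASIAN_THRESHOLDS
        for i in range(4):
            for m in range(12):
                for n in range(14):
                    r, g, b = frames[m, n, :, i]
                    expected = (
                        (t.r[0] < r <= t.r[1])
                        and (t.g[0] < g <= t.g[1])
                        and (t.b[0] < b <= t.b[1])
                    )
                    assert mask[m, n, i] == expected

    def test_mask_invariant_to_frame_order(self, rng):
        frames = rng.random((8, 8, 3, 5)).astype(np.float32)
        perm = [3, 1, 4, 0, 2]
        direct = skin_mask(FrameSequence(frames[:, :, :, perm], 30.0))
        permuted = skin_mask(FrameSequence(frames, 30.0))[:, :, perm]
        assert np.array_equal(direct, permuted)


class TestApplyMask:
    def test_all_ones_is_identity(self, rng):
        seq = FrameSequence(rng.random((6, 6, 3, 2)).astype(np.float32), 30.0)
        mask = np.ones((6, 6, 2), bool)
        assert np.array_equal(apply_mask(seq, mask).frames, seq.frames)

    def test_all_zeros_blanks_everything(self, rng):
        seq = FrameSequence(rng.random((6, 6, 3, 2)).astype(np.float32), 30.0)
        assert apply_mask(seq, np.zeros((6, 6, 2), bool)).frames.sum() == 0

    def test_checkerboard_halves_the_global_mean(self):
        seq = FrameSequence(np.full((8, 8, 3, 1), 0.7, np.float32), 30.0)
        mask = (np.indices((8, 8)).sum(axis=0) % 2)[:, :, None].astype(bool)
        out = apply_mask(seq, mask)
        assert out.frames.mean() == pytest.approx(0.35)


class TestRegionMeanBrightness:
    def _scene(self, coverage=1.0, red=0.7, n_frames=2, shape=(20, 40)):
        M, N = shape
        frames = np.zeros((M, N, 3, n_frames), np.float32)
        frames[:, :, 0] = red
        mask = np.zeros((M, N, n_frames), bool)
        rows = int(M * coverage)
        mask[:rows] = True
        return FrameSequence(frames, 30.0), mask

    def test_full_skin_constant_region(self):
        seq, mask = self._scene()
        sig = region_mean_brightness(
            seq, mask, RegionGrid(2, 4), min_skin_pixels=10
        )
        assert np.allclose(sig.traces, 0.7)
        assert sig.measurable.all()

    def test_partial_coverage_mean_over_skin_pixels_only(self):
        seq, mask = self._scene(coverage=0.25, red=0.8)
        sig = region_mean_brightness(
            seq, mask, RegionGrid(1, 1), min_skin_pixels=10
        )
        assert sig.traces[0, 0] == pytest.approx(0.8)

    def test_strict_area_denominator_scales_with_coverage(self):
        seq, mask = self._scene(coverage=0.25, red=0.8)
        sig = region_mean_brightness(
            seq, mask, RegionGrid(1, 1), min_skin_pixels=10,
            strict_area_denominator=True,
        )
        assert sig.traces[0, 0] == pytest.approx(0.2)

    def test_too_few_skin_pixels_flagged_unmeasurable(self):
        seq, mask = self._scene()
        mask[:, :, :] = False
        mask[0, :99] = True  # 99 < 100 minimum
        sig = region_mean_brightness(seq, mask, RegionGrid(1, 1))
        assert not sig.measurable[0]

    def test_mean_matches_independent_loop_summation(self, rng):
        frames = rng.random((16, 24, 3, 3)).astype(np.float32)
        seq = FrameSequence(frames, 30.0)
        mask = rng.random((16, 24, 3)) < 0.6
        grid = RegionGrid(2, 4)
        sig = region_mean_brightness(seq, mask, grid, min_skin_pixels=1)
        for r, (r0, r1, c0, c1) in enumerate(grid.bounds(16, 24)):
            for i in range(3):
                total, count = 0.0, 0
                for m in range(r0, r1):
                    for n in range(c0, c1):
                        if mask[m, n, i]:
                            total += float(frames[m, n, 0, i])
                            count += 1
                expected = total / count if count else np.nan
                if count:
                    assert abs(sig.traces[r, i] - expected) < 1e-12


class TestOtsu:
    def test_bimodal_frame_thresholds_separate_the_modes(self, rng):
        frames = np.zeros((20, 20, 3, 1), np.float32)
        frames[:10, :, 0, 0] = 0.2 + 0.01 * rng.random((10, 20))
        frames[10:, :, 0, 0] = 0.7 + 0.01 * rng.random((10, 20))
        p1, p2 = otsu_thresholds(FrameSequence(frames, 30.0))
        assert 0.2 < p1 < p2 < 0.72
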