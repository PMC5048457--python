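import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from skimage.feature import canny as sk_canny

from pulsecam.errors import ConfigurationError
from pulsecam.preprocess import (
    RegionGrid,
    Stabilizer,
    detect_edges,
    estimate_region_shift,
    median_filter_frame,
    median_filter_sequence,
    stabilize,
    translate_frame,
)
from pulsecam.synthetic import SceneConfig, generate_scene
from pulsecam.video_io import FrameSequence


class TestRegionGrid:
    @given(
        m=st.integers(16, 500),
        n=st.integers(16, 500),
        rows=st.integers(1, 4),
        cols=st.integers(1, 4),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_tiles_partition_the_frame_exactly(self, m, n, rows, cols):
        grid = RegionGrid(rows, cols)
        cover = np.zeros((m, n), int)
        for r0, r1, c0, c1 in grid.bounds(m, n):
            assert r1 > r0 and c1 > c0
            cover[r0:r1, c0:c1] += 1
        assert (cover == 1).all()

    def test_region_count(self):
        assert RegionGrid(4, 4).n_regions == 16
        assert RegionGrid(2, 4).n_regions == 8


class TestMedianFilter:
    def test_constant_frame_unchanged(self):
        frame = np.full((32, 32, 3), 0.5, np.float32)
        assert np.array_equal(median_filter_frame(frame), frame)

    def test_isolated_impulse_removed(self):
        frame = np.full((32, 32, 3), 0.5, np.float32)
        frame[15, 15] = 1.0
        out = median_filter_frame(frame)
        assert out[15, 15, 0] == pytest.approx(0.5)

    def test_four_pixel_cluster_fully_removed(self):
        # the largest noise cluster the camera produces (2×2 = 4 px) must
        # vanish under the 9×9 mask: the majority of each window is clean
        frame = np.full((40, 40, 3), 0.5, np.float32)
        frame[20:22, 20:22] = 1.0
        out = median_filter_frame(frame)
        assert np.abs(out - 0.5).max() == 0.0

    def test_histogram_kernel_matches_scipy_exactly(self, rng):
        # oracle equivalence: Huang sliding-histogram vs scipy rank filter
        for shape, mask in [((31, 45), (9, 9)), ((20, 20), (3, 5))]:
            img8 = rng.integers(0, 256, (*shape, 3), np.uint8)
            frame = img8.astype(np.float32) / 255.0
            ours = median_filter_frame(frame, *mask)
            ref = np.stack(
                [
                    ndimage.median_filter(img8[:, :, s], size=mask, mode="nearest")
                    for s in range(3)
                ],
                axis=-1,
            )
            assert np.array_equal(np.round(ours * 255).astype(np.uint8), ref)

    def test_float_fallback_matches_scipy(self, rng):
        frame = rng.random((20, 24, 3)).astype(np.float32) * 0.9 + 0.03
        ours = median_filter_frame(frame, 3, 3, assume_8bit=False)
        ref = np.stack(
            [
                ndimage.median_filter(frame[:, :, s], size=(3, 3), mode="nearest")
                for s in range(3)
            ],
            axis=-1,
        )
        assert np.allclose(ours, ref)

    def test_even_mask_rejected(self):
        with pytest.raises(ConfigurationError, match="odd"):
            median_filter_sequence(
                FrameSequence(np.zeros((8, 8, 3, 1), np.float32), 30.0), 8, 9
            )


class TestDetectEdges:
    def test_constant_frame_yields_empty_maps(self):
        assert detect_edges(np.full((32, 32, 3), 0.4, np.float32)).sum() == 0

    def test_vertical_step_edge_localized(self):
        frame = np.zeros((48, 48, 3), np.float32)
        frame[:, 24:] = 0.8
        edges = detect_edges(frame)
        for s in range(3):
            cols = np.where(edges[:, :, s].any(axis=0))[0]
            assert cols.size > 0
            assert np.all(np.abs(cols - 24) <= 1)

    def test_agrees_with_skimage_canny_on_step_edge(self):
        # independent reference detector localizes the same edge
        frame = np.zeros((48, 48, 3), np.float32)
        frame[:, 24:] = 0.8
        ref = sk_canny(frame[:, :, 0], sigma=1.0)
        ref_cols = np.where(ref.any(axis=0))[0]
        our_cols = np.where(detect_edges(frame)[:, :, 0].any(axis=0))[0]
        assert abs(np.median(our_cols) - np.median(ref_cols)) <= 1

    def test_ellipse_boundary_produces_edges(self, textured_frame):
        edges = detect_edges(textured_frame)
        assert edges.any()


def _brute_force_shift(ref, cur, max_shift):
    """Exhaustive inset-template ZNCC search (independent oracle)."""
    h, w = ref.shape[:2]
    T = cur[max_shift : h - max_shift, max_shift : w - max_shift].astype(float)
    T0 = T - T.mean()
    best, best_score = (0, 0), -np.inf
    for dm in range(-max_shift, max_shift + 1):
        for dn in range(-max_shift, max_shift + 1):
            p, q = max_shift - dm, max_shift - dn
            S = ref[p : p + T.shape[0], q : q + T.shape[1]].astype(float)
            S0 = S - S.mean()
            den = np.sqrt((S0**2).sum() * (T0**2).sum())
            score = (S0 * T0).sum() / den if den > 0 else 0.0
            key = (score, -(dm**2 + dn**2))
            if key > (best_score, -(best[0] ** 2 + best[1] ** 2)):
                best, best_score = (dm, dn), score
    return best, best_score


class TestEstimateRegionShift:
    def test_known_translation_recovered(self, rng):
        ref = rng.random((40, 50)) < 0.15
        cur = np.roll(ref, (3, -2), axis=(0, 1))
        shift = estimate_region_shift(ref, cur, max_shift=5)
        assert (shift.dm, shift.dn) == (3, -2)
        assert shift.informative

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            ref = rng.random((36, 44)) < 0.2
            cur = rng.random((36, 44)) < 0.2
            ours = estimate_region_shift(ref, cur, max_shift=4)
            oracle, oracle_score = _brute_force_shift(ref, cur, 4)
            assert ours.score == pytest.approx(oracle_score, abs=1e-6)
            assert (ours.dm, ours.dn) == oracle

    def test_identity_scores_maximally(self, rng):
        ref = rng.random((40, 50)) < 0.15
        shift = estimate_region_shift(ref, ref, max_shift=5)
        assert (shift.dm, shift.dn) == (0, 0)
        assert shift.score == pytest.approx(1.0, abs=1e-6)

    def test_empty_edges_flagged_uninformative(self, rng):
        ref = rng.random((40, 50)) < 0.15
        shift = estimate_region_shift(ref, np.zeros((40, 50), bool), max_shift=5)
        assert not shift.informative

    def test_region_too_small_rejected(self):
        with pytest.raises(ConfigurationError, match="small|overlap"):
            estimate_region_shift(
                np.ones((12, 12), bool), np.ones((12, 12), bool), max_shift=5
            )


class TestTranslateFrame:
    @given(dm=st.integers(-6, 6), dn=st.integers(-6, 6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_clipped_index_oracle(self, dm, dn):
        rng = np.random.default_rng(99)
        frame = rng.random((15, 19, 3)).astype(np.float32)
        rows = np.clip(np.arange(15) - dm, 0, 14)
        cols = np.clip(np.arange(19) - dn, 0, 18)
        assert np.array_equal(
            translate_frame(frame, dm, dn), frame[np.ix_(rows, cols)]
        )


class TestStabilize:
    def test_pure_translation_recovered_exactly(self, textured_frame):
        stab = Stabilizer(textured_frame, max_shift=5)
        moved = translate_frame(textured_frame, 5, -4)
        (dm, dn), _ = stab.offset_for(moved)
        assert (dm, dn) == (5, -4)

    def test_static_sequence_unchanged(self, textured_frame):
        frames = np.stack([textured_frame] * 4, axis=-1)
        seq = FrameSequence(frames, 30.0)
        out, result = stabilize(seq, max_shift=5)
        assert (result.offsets == 0).all()
        assert np.array_equal(out.frames, seq.frames)

    def test_noiseless_jitter_path_recovered_exactly(self):
        config = SceneConfig(
            duration_s=2.0,
            seed=3,
            noise_sigma=0.0,
            cluster_noise_per_frame=0,
            jitter_max_step=2,
            jitter_clamp=6,
        )
        seq, truth = generate_scene(config)
        _, result = stabilize(median_filter_sequence(seq))
        assert np.array_equal(result.offsets, truth.jitter)

    def test_noisy_jitter_reduced(self, small_scene):
        _, seq, truth = small_scene
        sub = FrameSequence(seq.frames[:, :, :, :90], seq.fps)
        _, result = stabilize(median_filter_sequence(sub), max_shift=5)
        residual = np.abs(result.offsets - truth.jitter[:90]).mean()
        assert residual < np.abs(truth.jitter[:90]).mean()

    def test_offsets_clamped_to_search_limit(self, small_scene):
        _, seq, _ = small_scene
        sub = FrameSequence(seq.frames[:, :, :, :30], seq.fps)
        _, result = stabilize(median_filter_sequence(sub), max_shift=5)
        assert np.abs(result.offsets).max() <= 5

    def test_stabilizing_twice_is_idempotent(self, textured_frame):
        jittered = [
            textured_frame,
            translate_frame(textured_frame, 2, 1),
            translate_frame(textured_frame, -1, 2),
        ]
        once, r1 = stabilize(FrameSequence.from_frames(jittered, 30.0), max_shift=5)
        twice, r2 = stabilize(once, max_shift=5)
        assert (r2.offsets == 0).all()

    def test_result_dataframe_schema(self, textured_frame):
        seq = FrameSequence(np.stack([textured_frame] * 3, axis=-1), 30.0)
        _, result = stabilize(seq, max_shift=5)
        df = result.to_dataframe()
        assert list(df.columns) == [
            "frame_index", "dm", "dn", "n_informative_regions",
        ]
        assert len(df) == 3
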