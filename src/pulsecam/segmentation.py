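"""Skin segmentation and per-region brightness signal extraction.

Skin pixels are found by two-threshold binarization of each RGB channel —
a pixel belongs to the channel mask when its brightness lies strictly above
the lower threshold and at or below the upper one — and the per-channel
masks are combined with a logical AND.  Defaults are the Caucasian skin
brightness ranges R ∈ (0.59, 0.78], G, B ∈ (0.48, 0.63]; a multi-level Otsu
variant can derive the red-channel thresholds from the first frame instead.

The masked, stabilized frames are then divided into 8 equal regions and the
mean red-channel brightness of each region's skin pixels is tracked over
time; these per-region traces are the input to the pulse spectral analysis.
A region needs at least ``min_skin_pixels`` (default 100) skin pixels to be
measurable at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_multiotsu

from .errors import ConfigurationError, ShapeMismatchError
from .preprocess import RegionGrid
from .video_io import FrameSequence

__all__ = [
    "ChannelThresholds",
    "CAUCASIAN_THRESHOLDS",
    "RegionSignal",
    "SIGNAL_GRID_SHAPE",
    "MIN_SKIN_PIXELS",
    "binarize_channel",
    "combine_masks",
    "skin_mask",
    "apply_mask",
    "region_mean_brightness",
    "otsu_thresholds",
]

CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}

#: Default grid for signal extraction (8 regions, 2 rows × 4 columns).
SIGNAL_GRID_SHAPE = (2, 4)

#: Below this many skin pixels a region admits no measurement.
MIN_SKIN_PIXELS = 100


@dataclass(frozen=True)
class ChannelThresholds:
    """Per-channel two-threshold brightness ranges ``p1 < value <= p2``."""

    r: tuple[float, float] = (0.59, 0.78)
    g: tuple[float, float] = (0.48, 0.63)
    b: tuple[float, float] = (0.48, 0.63)

    def __post_init__(self) -> None:
        for name, (p1, p2) in zip("rgb", (self.r, self.g, self.b)):
            if not (0.0 <= p1 < p2 <= 1.0):
                raise ConfigurationError(
                    f"channel {name.upper()}: need 0 <= p1 < p2 <= 1, got ({p1}, {p2})"
                )

    def for_channel(self, channel: str) -> tuple[float, float]:
        return {"R": self.r, "G": self.g, "B": self.b}[channel.upper()]

    def contains(self, color) -> bool:
        """True when an (R, G, B) colour lies inside all three ranges."""
        return all(
            p1 < c <= p2
            for c, (p1, p2) in zip(color, (self.r, self.g, self.b))
        )


#: Skin brightness ranges for Caucasian skin under 200–500 lx lighting.
CAUCASIAN_THRESHOLDS = ChannelThresholds()


def _channel_values(seq, channel: str) -> np.ndarray:
    frames = seq.frames if isinstance(seq, FrameSequence) else np.asarray(seq)
    return frames[:, :, CHANNEL_INDEX[channel.upper()], :]


def binarize_channel(seq, channel: str, p1: float, p2: float) -> np.ndarray:
    """Two-threshold binarization of one channel: 1 where ``p1 < v <= p2``.

    Returns a boolean per-frame mask array of shape ``(M, N, I)``.  The
    lower comparison is strict and the upper inclusive, so a value exactly
    at ``p1`` is background while one exactly at ``p2`` is skin.
    """
    if not p1 < p2:
        raise ConfigurationError(f"need p1 < p2, got p1={p1}, p2={p2}")
    v = _channel_values(seq, channel)
    return (v > p1) & (v <= p2)


def combine_masks(
    mask_r: np.ndarray, mask_g: np.ndarray, mask_b: np.ndarray
) -> np.ndarray:
    """Pixelwise AND of the three per-channel binary masks."""
    if not (mask_r.shape == mask_g.shape == mask_b.shape):
        raise ShapeMismatchError(
            f"mask shapes differ: {mask_r.shape}, {mask_g.shape}, {mask_b.shape}"
        )
    return mask_r.astype(bool) & mask_g.astype(bool) & mask_b.astype(bool)


def skin_mask(
    seq, thresholds: ChannelThresholds = CAUCASIAN_THRESHOLDS
) -> np.ndarray:
    """Per-frame skin mask ``(M, N, I)`` from the three channel ranges."""
    return combine_masks(
        binarize_channel(seq, "R", *thresholds.r),
        binarize_channel(seq, "G", *thresholds.g),
        binarize_channel(seq, "B", *thresholds.b),
    )


def apply_mask(seq: FrameSequence, mask: np.ndarray) -> FrameSequence:
    """Zero out non-skin pixels in every channel (pixelwise product)."""
    M, N = seq.shape
    if mask.shape != (M, N, seq.n_frames):
        raise ShapeMismatchError(
            f"mask shape {mask.shape} does not match frames "
            f"{(M, N, seq.n_frames)}"
        )
    out = seq.frames * mask[:, :, None, :]
    return FrameSequence(out.astype(seq.frames.dtype), seq.fps)


def otsu_thresholds(seq, channel: str = "R") -> tuple[float, float]:
    """Automatic two-threshold variant: multi-level Otsu on the first frame.

    Splits the channel histogram of frame 1 into three classes and returns
    the two separating thresholds, usable in place of the fixed ranges.
    """
    v = _channel_values(seq, channel)[:, :, 0]
    t1, t2 = threshold_multiotsu(v, classes=3)
    return float(t1), float(t2)


@dataclass
class RegionSignal:
    """Per-region mean-brightness time series and skin-pixel bookkeeping.

    ``traces[r, i]`` is the mean brightness of the analysed channel over the
    skin pixels of region ``r`` in frame ``i`` (NaN when the region has no
    skin pixels in that frame); ``counts[r, i]`` the skin-pixel count.  A
    region is ``measurable`` when it never drops below ``min_skin_pixels``.
    """

    traces: np.ndarray  # (R, I) float
    counts: np.ndarray  # (R, I) int
    fps: float
    grid: RegionGrid = field(default=RegionGrid(*SIGNAL_GRID_SHAPE))
    min_skin_pixels: int = MIN_SKIN_PIXELS
    channel: str = "R"

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def n_regions(self) -> int:
        return self.traces.shape[0]

    @property
    def measurable(self) -> np.ndarray:
        """Boolean per region: enough skin pixels in every frame."""
        return self.counts.min(axis=1) >= self.min_skin_pixels

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.traces.T,
            columns=[f"region_{r + 1}" for r in range(self.n_regions)],
        )
        df.insert(0, "frame_index", np.arange(self.n_frames))
        return df

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            counts = ",".join(str(int(c)) for c in self.counts.min(axis=1))
            fh.write(f"# min_skin_pixel_count_per_region,{counts}\n")
            self.to_dataframe().to_csv(fh, index=False)


def region_sums(
    frame: np.ndarray,
    mask: np.ndarray,
    bounds: list[tuple[int, int, int, int]],
    channel_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region sum of one channel over skin pixels, and skin counts.

    Streaming building block for :func:`region_mean_brightness`; ``frame``
    is ``(M, N, 3)``, ``mask`` ``(M, N)``.
    """
    sums = np.empty(len(bounds))
    counts = np.empty(len(bounds), dtype=np.int64)
    v = frame[:, :, channel_index]
    for r, (r0, r1, c0, c1) in enumerate(bounds):
        m = mask[r0:r1, c0:c1]
        counts[r] = int(m.sum())
        # accumulate in double precision: the mean must match an
        # independent summation loop to 1e-12
        sums[r] = (
            float(v[r0:r1, c0:c1][m].sum(dtype=np.float64)) if counts[r] else 0.0
        )
    return sums, counts


def region_mean_brightness(
    seq: FrameSequence,
    mask: np.ndarray,
    grid: RegionGrid | None = None,
    channel: str = "R",
    min_skin_pixels: int = MIN_SKIN_PIXELS,
    strict_area_denominator: bool = False,
) -> RegionSignal:
    """Mean brightness of the chosen channel over each region's skin pixels.

    By default the denominator is the region's skin-pixel count, so the mean
    is invariant to how much of the region the skin covers.  With
    ``strict_area_denominator=True`` the masked sum is divided by the full
    region area instead (the literal masked-sum-over-area convention), which
    scales the signal by the coverage fraction.  Regions short of
    ``min_skin_pixels`` in any frame are flagged unmeasurable, not raised.
    """
    grid = grid or RegionGrid(*SIGNAL_GRID_SHAPE)
    M, N = seq.shape
    if mask.shape != (M, N, seq.n_frames):
        raise ShapeMismatchError(
            f"mask shape {mask.shape} does not match frames {(M, N, seq.n_frames)}"
        )
    bounds = grid.bounds(M, N)
    ci = CHANNEL_INDEX[channel.upper()]
    R, I = grid.n_regions, seq.n_frames
    traces = np.empty((R, I))
    counts = np.empty((R, I), dtype=np.int64)
    areas = np.array([(r1 - r0) * (c1 - c0) for r0, r1, c0, c1 in bounds])
    for i in range(I):
        s, c = region_sums(seq.frame(i), mask[:, :, i], bounds, ci)
        counts[:, i] = c
        with np.errstate(invalid="ignore", divide="ignore"):
            traces[:, i] = s / areas if strict_area_denominator else s / c
    traces[counts == 0] = np.nan if not strict_area_denominator else 0.0
    return RegionSignal(
        traces, counts, seq.fps, grid, min_skin_pixels, channel.upper()
    )
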