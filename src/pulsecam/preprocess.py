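"""Image pre-processing: median filtering and edge-correlation stabilization.

The camera is assumed to sit still while the subject (and hence the whole
scene content) drifts by a few pixels; single noise clusters cover at most
4 pixels.  Accordingly each frame is first cleaned with a 9×9 median filter,
then the sequence is stabilized: every frame is divided into 16 equal
regions, each region's per-channel Canny edge map is correlated against the
corresponding region of the first frame over all integer shifts within
±``max_shift`` pixels, and the informative regions' best shifts are averaged
into one global offset that is undone by translating the frame.

The reference-frame FFTs and window statistics are precomputed once in a
:class:`Stabilizer`, so per-frame cost is one edge detection plus one batched
FFT correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy import ndimage

from ._kernels import gaussian_gradients_2d, median_u8, nms_hysteresis
from .errors import ConfigurationError, ShapeMismatchError
from .video_io import FrameSequence

__all__ = [
    "RegionGrid",
    "StabilizationResult",
    "RegionShift",
    "Stabilizer",
    "median_filter_frame",
    "median_filter_sequence",
    "detect_edges",
    "estimate_region_shift",
    "stabilize",
    "translate_frame",
]

logger = logging.getLogger(__name__)

#: Default grid used for stabilization (16 regions).
STABILIZATION_GRID_SHAPE = (4, 4)


@dataclass(frozen=True)
class RegionGrid:
    """Partition of a frame into ``n_rows × n_cols`` equal rectangular tiles.

    Tiles cover the frame exactly with no overlap; when a dimension does not
    divide evenly the tile edges are placed at ``floor(k * size / n)`` so
    tile sizes differ by at most one pixel.
    """

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid must have at least one row and column")

    @property
    def n_regions(self) -> int:
        return self.n_rows * self.n_cols

    def bounds(self, M: int, N: int) -> list[tuple[int, int, int, int]]:
        """Half-open pixel bounds ``(r0, r1, c0, c1)`` per region, row-major."""
        re = [(k * M) // self.n_rows for k in range(self.n_rows + 1)]
        ce = [(k * N) // self.n_cols for k in range(self.n_cols + 1)]
        return [
            (re[a], re[a + 1], ce[b], ce[b + 1])
            for a in range(self.n_rows)
            for b in range(self.n_cols)
        ]


class RegionShift(NamedTuple):
    """Best integer shift of one region against the reference frame."""

    dm: int
    dn: int
    score: float
    informative: bool


# ---------------------------------------------------------------------------
# median filtering
# ---------------------------------------------------------------------------

def _is_8bit_grid(frame: np.ndarray) -> bool:
    q = frame * 255.0
    return bool(np.abs(q - np.round(q)).max() < 1e-4)

def _check_mask(mask_rows: int, mask_cols: int) -> None:
    if mask_rows < 1 or mask_cols < 1 or mask_rows % 2 == 0 or mask_cols % 2 == 0:
        raise ConfigurationError(
            f"median mask dimensions must be odd and >= 1, got {mask_rows}x{mask_cols}"
        )


def median_filter_frame(
    frame: np.ndarray,
    mask_rows: int = 9,
    mask_cols: int = 9,
    assume_8bit: bool | None = None,
) -> np.ndarray:
    """Per-channel 2-D median filter of one ``(M, N, 3)`` frame.

    Borders are edge-replicated.  For brightness on the 8-bit grid (the
    camera's native 256 levels) an exact histogram-based kernel is used;
    other data falls back to :func:`scipy.ndimage.median_filter`.
    """
    _check_mask(mask_rows, mask_cols)
    if mask_rows == 1 and mask_cols == 1:
        return frame.copy()
    if assume_8bit is None:
        assume_8bit = _is_8bit_grid(frame)
    out = np.empty_like(frame, dtype=np.float32)
    if assume_8bit:
        u8 = np.round(frame * 255.0).astype(np.uint8)
        buf = np.empty(frame.shape[:2], np.uint8)
        pm, pn = mask_rows // 2, mask_cols // 2
        for s in range(frame.shape[2]):
            padded = np.pad(u8[:, :, s], ((pm, pm), (pn, pn)), mode="edge")
            median_u8(padded, mask_rows, mask_cols, buf)
            out[:, :, s] = buf.astype(np.float32) / 255.0
    else:
        for s in range(frame.shape[2]):
            out[:, :, s] = ndimage.median_filter(
                frame[:, :, s], size=(mask_rows, mask_cols), mode="nearest"
            )
    return out


def median_filter_sequence(
    seq: FrameSequence, mask_rows: int = 9, mask_cols: int = 9
) -> FrameSequence:
    """Median-filter every frame of a sequence (the L_MED stage)."""
    _check_mask(mask_rows, mask_cols)
    assume = _is_8bit_grid(seq.frames)
    out = np.empty_like(seq.frames, dtype=np.float32)
    for i in range(seq.n_frames):
        out[:, :, :, i] = median_filter_frame(
            seq.frame(i), mask_rows, mask_cols, assume_8bit=assume
        )
    return FrameSequence(out, seq.fps)


# ---------------------------------------------------------------------------
# edge detection
# ---------------------------------------------------------------------------

_KERNEL_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _gaussian_kernels(sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Gaussian and Gaussian-derivative kernels (radius 4σ)."""
    if sigma not in _KERNEL_CACHE:
        radius = max(int(4.0 * sigma + 0.5), 1)
        x = np.arange(-radius, radius + 1, dtype=np.float64)
        g = np.exp(-0.5 * (x / sigma) ** 2)
        g /= g.sum()
        dg = -x / sigma**2 * g
        _KERNEL_CACHE[sigma] = (g.astype(np.float32), dg.astype(np.float32))
    return _KERNEL_CACHE[sigma]


def detect_edges(
    frame: np.ndarray,
    sigma: float = 1.0,
    high_quantile: float = 0.90,
    low_fraction: float = 0.40,
) -> np.ndarray:
    """Per-channel Canny edge maps of an ``(M, N, 3)`` frame in ``[0, 1]``.

    Gaussian-derivative gradients (``sigma``), direction-quantized
    non-maximum suppression, and hysteresis thresholding with thresholds
    derived per channel from the gradient-magnitude distribution: the high
    threshold is its ``high_quantile`` quantile, the low one
    ``low_fraction`` of that.  A constant channel yields an empty map.
    """
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ShapeMismatchError(f"expected (M, N, 3) frame, got {frame.shape}")
    k_smooth, k_deriv = _gaussian_kernels(sigma)
    radius = k_smooth.size // 2
    M, N = frame.shape[:2]
    n = M * N
    kth = min(n - 1, int(high_quantile * n))
    gx = np.empty((M, N), np.float32)
    gy = np.empty((M, N), np.float32)
    mag = np.empty((M, N), np.float32)
    out = np.zeros((M, N, 3), bool)
    for s in range(3):
        padded = np.pad(
            np.ascontiguousarray(frame[:, :, s], dtype=np.float32),
            radius, mode="edge",
        )
        gaussian_gradients_2d(padded, k_smooth, k_deriv, gx, gy, mag)
        high = float(np.partition(mag.ravel(), kth)[kth])
        if high <= 1e-7:  # essentially constant channel
            continue
        chan = np.zeros((M, N), bool)
        nms_hysteresis(mag, gx, gy, high, low_fraction * high, chan)
        out[:, :, s] = chan
    return out


# ---------------------------------------------------------------------------
# shift estimation / stabilization
# ---------------------------------------------------------------------------

def translate_frame(frame: np.ndarray, dm: int, dn: int) -> np.ndarray:
    """Shift frame content by ``(dm, dn)`` pixels (down, right), replicating
    edge pixels into the vacated border."""
    M, N = frame.shape[:2]
    out = np.empty_like(frame)
    sr = slice(max(dm, 0), M + min(dm, 0))
    ss = slice(max(-dm, 0), M + min(-dm, 0))
    tc = slice(max(dn, 0), N + min(dn, 0))
    sc = slice(max(-dn, 0), N + min(-dn, 0))
    out[sr, tc] = frame[ss, sc]
    if dm > 0:
        out[:dm] = out[dm]
    elif dm < 0:
        out[dm:] = out[dm - 1]
    if dn > 0:
        out[:, :dn] = out[:, dn : dn + 1]
    elif dn < 0:
        out[:, dn:] = out[:, dn - 1 : dn]
    return out


def max_feasible_shift(region_rows: int, region_cols: int, want: int) -> int:
    """Largest search range ≤ ``want`` that the region size supports.

    The inset template must keep at least 2 px per axis and ≥ 50 % of the
    region area as overlap.  Returns 0 when no shift search is possible.
    """
    for ms in range(min(want, (region_rows - 2) // 2, (region_cols - 2) // 2), 0, -1):
        th, tw = region_rows - 2 * ms, region_cols - 2 * ms
        if th * tw >= 0.5 * region_rows * region_cols - 1e-9:
            return ms
    return 0


def _as_edge_stack(edges: np.ndarray) -> np.ndarray:
    if edges.ndim == 2:
        edges = edges[:, :, None]
    if edges.ndim != 3:
        raise ShapeMismatchError(f"edge maps must be (h, w[, channels]), got {edges.shape}")
    return edges.astype(bool)


class _RegionMatcher:
    """Batched zero-mean NCC shift search of region edge maps.

    The current frame's region is inset by ``max_shift`` on every side and
    used as the template; it is slid over the full reference region, so the
    overlap area is constant and equals the template.  FFTs and window
    statistics of the (fixed) reference are computed once.
    """

    def __init__(self, ref_edges: np.ndarray, grid: RegionGrid, max_shift: int):
        ref_edges = _as_edge_stack(ref_edges)
        M, N, C = ref_edges.shape
        self.grid = grid
        self.max_shift = int(max_shift)
        self.C = C
        if self.max_shift < 1:
            raise ConfigurationError("max_shift must be >= 1")
        # common region shape: tiles may differ by 1 px, crop to the minimum
        self.h = M // grid.n_rows
        self.w = N // grid.n_cols
        ms = self.max_shift
        self.th, self.tw = self.h - 2 * ms, self.w - 2 * ms
        if self.th < 2 or self.tw < 2:
            raise ConfigurationError(
                f"regions of {self.h}x{self.w} px are too small to search "
                f"±{ms} px shifts"
            )
        if self.th * self.tw < 0.5 * self.h * self.w - 1e-9:
            raise ConfigurationError(
                f"±{ms} px search leaves less than 50% overlap for "
                f"{self.h}x{self.w} px regions"
            )
        self.bounds = grid.bounds(M, N)
        S = self._region_batch(ref_edges)  # (R*C, h, w) float32
        self.ref_has_edges = S.reshape(grid.n_regions, C, -1).sum(axis=2) > 0
        self.FS = sfft.rfft2(S, axes=(1, 2))
        # sliding-window sums of the binary reference over template-size
        # windows at every candidate position (integral image)
        ii = np.zeros((S.shape[0], self.h + 1, self.w + 1), np.float64)
        np.cumsum(S, axis=1, out=ii[:, 1:, 1:])
        np.cumsum(ii[:, 1:, 1:], axis=2, out=ii[:, 1:, 1:])
        k = 2 * ms + 1
        p = np.arange(k)
        winsum = (
            ii[:, p[:, None] + self.th, p[None, :] + self.tw]
            - ii[:, p[:, None] + self.th, p[None, :]]
            - ii[:, p[:, None], p[None, :] + self.tw]
            + ii[:, p[:, None], p[None, :]]
        )
        n_t = self.th * self.tw
        var = winsum - winsum**2 / n_t  # sum of squares == sum for binary maps
        self.den_ref = np.sqrt(np.maximum(var, 0.0))

    def _region_batch(self, edges: np.ndarray) -> np.ndarray:
        gr, gc = self.grid.n_rows, self.grid.n_cols
        M, N, C = edges.shape
        if M == gr * self.h and N == gc * self.w:  # grid divides evenly
            return (
                edges.reshape(gr, self.h, gc, self.w, C)
                .transpose(0, 2, 4, 1, 3)
                .reshape(gr * gc * C, self.h, self.w)
                .astype(np.float32)
            )
        parts = [
            edges[r0 : r0 + self.h, c0 : c0 + self.w, s]
            for (r0, _, c0, _) in self.bounds
            for s in range(self.C)
        ]
        return np.stack(parts).astype(np.float32)

    def match(self, cur_edges: np.ndarray) -> list[RegionShift]:
        cur_edges = _as_edge_stack(cur_edges)
        ms, th, tw = self.max_shift, self.th, self.tw
        R, C = self.grid.n_regions, self.C
        T = self._region_batch(cur_edges)[:, ms : ms + th, ms : ms + tw]
        sumT = T.reshape(R * C, -1).sum(axis=1)
        n_t = th * tw
        norm_t = np.sqrt(np.maximum(sumT - sumT**2 / n_t, 0.0))
        T0 = T - (sumT / n_t)[:, None, None]
        Tp = np.zeros((R * C, self.h, self.w), np.float32)
        Tp[:, :th, :tw] = T0
        corr = sfft.irfft2(
            self.FS * np.conj(sfft.rfft2(Tp, axes=(1, 2))),
            s=(self.h, self.w), axes=(1, 2),
        )[:, : 2 * ms + 1, : 2 * ms + 1]
        den = self.den_ref * norm_t[:, None, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(den > 1e-9, corr / np.maximum(den, 1e-30), 0.0)
        cur_has_edges = sumT.reshape(R, C) > 0
        ch_ok = self.ref_has_edges & cur_has_edges  # (R, C)
        score = score.reshape(R, C, 2 * ms + 1, 2 * ms + 1)
        out = []
        for r in range(R):
            ok = ch_ok[r]
            if not ok.any():
                out.append(RegionShift(0, 0, float("nan"), False))
                continue
            sc = score[r, ok].mean(axis=0)
            out.append(self._pick(sc))
        return out

    def _pick(self, sc: np.ndarray) -> RegionShift:
        ms = self.max_shift
        flat = sc.ravel()
        k = int(flat.argmax())
        mx = float(flat[k])
        tied = flat >= mx - 1e-9
        if tied.sum() == 1:  # unique maximum: no tie-breaking needed
            p, q = divmod(k, sc.shape[1])
            return RegionShift(ms - p, ms - q, mx, True)
        cand = np.argwhere(tied.reshape(sc.shape))
        dm = ms - cand[:, 0]
        dn = ms - cand[:, 1]
        # smallest shift magnitude first, then row-major position order
        best = np.lexsort((cand[:, 1], cand[:, 0], dm**2 + dn**2))[0]
        return RegionShift(int(dm[best]), int(dn[best]), mx, True)


def estimate_region_shift(
    ref_edges: np.ndarray, cur_edges: np.ndarray, max_shift: int = 10
) -> RegionShift:
    """Best integer shift of one region's edge maps against the reference.

    Exhaustive search over ``[-max_shift, max_shift]²`` maximizing the
    channel-averaged zero-mean normalized cross-correlation over the
    (constant-size) overlap.  Ties are broken toward the smallest shift
    magnitude, then row-major order.  Regions whose edge maps are empty in
    either input are flagged uninformative.
    """
    ref_edges = _as_edge_stack(ref_edges)
    cur_edges = _as_edge_stack(cur_edges)
    if ref_edges.shape != cur_edges.shape:
        raise ShapeMismatchError(
            f"edge map shapes differ: {ref_edges.shape} vs {cur_edges.shape}"
        )
    matcher = _RegionMatcher(ref_edges, RegionGrid(1, 1), max_shift)
    return matcher.match(cur_edges)[0]


@dataclass
class StabilizationResult:
    """Applied offsets and per-region correlation peaks for a sequence."""

    offsets: np.ndarray  # (I, 2) int, applied (dm, dn) per frame
    region_shifts: np.ndarray  # (I, R, 2) float, NaN where uninformative
    informative: np.ndarray  # (I, R) bool
    max_shift: int
    grid: RegionGrid = field(default=RegionGrid(*STABILIZATION_GRID_SHAPE))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(self.offsets.shape[0]),
                "dm": self.offsets[:, 0],
                "dn": self.offsets[:, 1],
                "n_informative_regions": self.informative.sum(axis=1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class Stabilizer:
    """Incremental stabilizer locked onto the first (reference) frame.

    Feed median-filtered frames to :meth:`offset_for` in temporal order; it
    returns the offset of the frame's content relative to the reference.
    Frames where all regions are uninformative inherit the previous offset.
    """

    def __init__(
        self,
        ref_frame: np.ndarray,
        grid: RegionGrid | None = None,
        max_shift: int = 10,
        **canny_kwargs,
    ):
        self.grid = grid or RegionGrid(*STABILIZATION_GRID_SHAPE)
        self.canny_kwargs = canny_kwargs
        ref_edges = detect_edges(ref_frame, **canny_kwargs)
        self.matcher = _RegionMatcher(ref_edges, self.grid, max_shift)
        self.max_shift = int(max_shift)
        self._prev = (0, 0)

    def offset_for(
        self, frame: np.ndarray | None = None, edges: np.ndarray | None = None
    ) -> tuple[tuple[int, int], list[RegionShift]]:
        """Estimate the content offset of ``frame`` (or precomputed edge
        maps) relative to the reference frame."""
        if edges is None:
            if frame is None:
                raise ConfigurationError("pass a frame or its edge maps")
            edges = detect_edges(frame, **self.canny_kwargs)
        shifts = self.matcher.match(edges)
        good = [s for s in shifts if s.informative]
        if not good:
            logger.warning(
                "all %d regions uninformative; reusing previous offset %s",
                self.grid.n_regions, self._prev,
            )
            return self._prev, shifts
        # robust mean: regions whose edge content is a smooth arc can lock
        # onto a spurious shift with a perfect correlation score (aperture
        # problem), so average only the regions within 1 px of the per-axis
        # median shift
        dms = np.array([s.dm for s in good], float)
        dns = np.array([s.dn for s in good], float)
        inlier = (np.abs(dms - np.median(dms)) <= 1.0) & (
            np.abs(dns - np.median(dns)) <= 1.0
        )
        if not inlier.any():
            inlier[:] = True
        dm = float(dms[inlier].mean())
        dn = float(dns[inlier].mean())
        # round half away from zero, clamp to the search limit
        rnd = lambda x: int(np.sign(x) * np.floor(abs(x) + 0.5))  # noqa: E731
        off = (
            int(np.clip(rnd(dm), -self.max_shift, self.max_shift)),
            int(np.clip(rnd(dn), -self.max_shift, self.max_shift)),
        )
        self._prev = off
        return off, shifts


def stabilize(
    seq: FrameSequence,
    grid: RegionGrid | None = None,
    max_shift: int = 10,
    **canny_kwargs,
) -> tuple[FrameSequence, StabilizationResult]:
    """Stabilize a (median-filtered) sequence against its first frame.

    Per frame, the informative regions' best shifts are averaged, rounded to
    integers, and undone by translating the frame (edge replication fills
    the vacated border).  The first frame is returned unchanged.
    """
    grid = grid or RegionGrid(*STABILIZATION_GRID_SHAPE)
    stab = Stabilizer(seq.frame(0), grid, max_shift, **canny_kwargs)
    I = seq.n_frames
    R = grid.n_regions
    offsets = np.zeros((I, 2), int)
    region_shifts = np.full((I, R, 2), np.nan)
    informative = np.zeros((I, R), bool)
    informative[0] = True
    region_shifts[0] = 0.0
    out = np.empty_like(seq.frames, dtype=np.float32)
    out[:, :, :, 0] = seq.frame(0)
    for i in range(1, I):
        frame = seq.frame(i)
        (dm, dn), shifts = stab.offset_for(frame)
        offsets[i] = (dm, dn)
        for r, s in enumerate(shifts):
            informative[i, r] = s.informative
            if s.informative:
                region_shifts[i, r] = (s.dm, s.dn)
        out[:, :, :, i] = translate_frame(frame, -dm, -dn)
    return (
        FrameSequence(out, seq.fps),
        StabilizationResult(offsets, region_shifts, informative, max_shift, grid),
    )
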