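"""End-to-end measurement pipeline.

The three stages — median filtering + stabilization, skin segmentation +
region signal extraction, and spectral pulse estimation — are composed here.
The runner is streaming: frames are consumed one at a time (from a
:class:`~pulsecam.video_io.FrameSequence`, a generator, or the synthetic
simulator), only the per-region traces are accumulated, and the spectral
analysis runs once at the end.  Memory use is therefore independent of the
recording length, which matters for multi-minute clips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import UnmeasurableInputError
from .preprocess import (
    STABILIZATION_GRID_SHAPE,
    RegionGrid,
    StabilizationResult,
    Stabilizer,
    _is_8bit_grid,
    max_feasible_shift,
    median_filter_frame,
    translate_frame,
)
from .pulse_signal import PulseConfig, PulseTrace, pulse_trace
from .segmentation import (
    CAUCASIAN_THRESHOLDS,
    MIN_SKIN_PIXELS,
    SIGNAL_GRID_SHAPE,
    ChannelThresholds,
    RegionSignal,
    region_sums,
)
from .video_io import FrameSequence

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the full measurement pipeline."""

    median_mask: tuple[int, int] = (9, 9)
    stabilize: bool = True
    stabilization_grid: tuple[int, int] = STABILIZATION_GRID_SHAPE
    max_shift: int = 10
    canny_sigma: float = 1.0
    canny_high_quantile: float = 0.90
    canny_low_fraction: float = 0.40
    thresholds: ChannelThresholds = CAUCASIAN_THRESHOLDS
    signal_grid: tuple[int, int] = SIGNAL_GRID_SHAPE
    channel: str = "R"
    min_skin_pixels: int = MIN_SKIN_PIXELS
    strict_area_denominator: bool = False
    pulse: PulseConfig = field(default_factory=PulseConfig)


@dataclass
class PipelineResult:
    """Everything the pipeline measured on one recording."""

    traces: list[PulseTrace]
    region_signal: RegionSignal
    stabilization: StabilizationResult
    config: PipelineConfig
    fps: float

    @property
    def measurable_regions(self) -> np.ndarray:
        return self.region_signal.measurable

    def pooled_significant(self) -> np.ndarray:
        """All significant pulse readings from measurable regions, pooled."""
        vals = [
            t.significant_values()
            for t, ok in zip(self.traces, self.measurable_regions)
            if ok
        ]
        return np.concatenate(vals) if vals else np.empty(0)

    def median_bpm(self) -> float:
        """Median significant pulse over all measurable regions (NaN if none)."""
        v = self.pooled_significant()
        return float(np.median(v)) if v.size else float("nan")

    def require_measurable(self) -> None:
        if not self.measurable_regions.any():
            raise UnmeasurableInputError(
                "no skin region with at least "
                f"{self.config.min_skin_pixels} skin pixels was detected"
            )


def _channel_masks(frame: np.ndarray, thresholds: ChannelThresholds):
    ranges = (thresholds.r, thresholds.g, thresholds.b)
    mask = np.ones(frame.shape[:2], bool)
    for s, (p1, p2) in enumerate(ranges):
        v = frame[:, :, s]
        mask &= (v > p1) & (v <= p2)
    return mask


def run_pipeline(
    frames: FrameSequence | Iterable[np.ndarray],
    fps: float | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run median filter → stabilization → segmentation → pulse estimation.

    ``frames`` is a :class:`FrameSequence` or any iterable of ``(M, N, 3)``
    frames in ``[0, 1]`` (then ``fps`` is required).  Stages follow the
    frame order: each frame is median-filtered, its offset against the
    first frame is estimated from 16-region edge correlation and undone,
    the stabilized frame is segmented with the two-threshold colour ranges,
    and the mean red-channel brightness of each of the 8 signal regions'
    skin pixels is appended to that region's trace.  The traces then go
    through the band-pass + sliding-FFT estimator.
    """
    if isinstance(frames, FrameSequence):
        fps = frames.fps
        frame_iter = frames.iter_frames()
    else:
        if fps is None:
            raise ValueError("fps is required when passing a frame iterable")
        frame_iter = iter(frames)

    stab_grid = RegionGrid(*config.stabilization_grid)
    sig_grid = RegionGrid(*config.signal_grid)
    mh, mn = config.median_mask
    ci = {"R": 0, "G": 1, "B": 2}[config.channel.upper()]

    stabilizer: Stabilizer | None = None
    bounds = None
    offsets = []
    region_list = []
    informative = []
    sums = []
    counts = []
    canny_kwargs = dict(
        sigma=config.canny_sigma,
        high_quantile=config.canny_high_quantile,
        low_fraction=config.canny_low_fraction,
    )
    assume_8bit = None
    for i, frame in enumerate(frame_iter):
        filtered = median_filter_frame(frame, mh, mn, assume_8bit=assume_8bit)
        if i == 0:
            assume_8bit = _is_8bit_grid(frame)  # decide once per recording
            M, N = filtered.shape[:2]
            bounds = sig_grid.bounds(M, N)
            if config.stabilize:
                # tiny frames cannot support the full ±max_shift search;
                # clamp to what the region size allows, or skip entirely
                ms = max_feasible_shift(
                    M // stab_grid.n_rows, N // stab_grid.n_cols, config.max_shift
                )
                if ms < config.max_shift:
                    warnings.warn(
                        f"search range clamped from ±{config.max_shift} to "
                        f"±{ms} px for {M}x{N} frames"
                        if ms
                        else f"frames of {M}x{N} px are too small to "
                        "stabilize; stabilization skipped",
                        stacklevel=2,
                    )
                if ms:
                    stabilizer = Stabilizer(filtered, stab_grid, ms, **canny_kwargs)
            offsets.append((0, 0))
            informative.append([True] * stab_grid.n_regions)
            region_list.append([(0.0, 0.0)] * stab_grid.n_regions)
            stabilized = filtered
        elif stabilizer is not None:
            (dm, dn), shifts = stabilizer.offset_for(filtered)
            offsets.append((dm, dn))
            informative.append([s.informative for s in shifts])
            region_list.append(
                [
                    (s.dm, s.dn) if s.informative else (np.nan, np.nan)
                    for s in shifts
                ]
            )
            stabilized = (
                translate_frame(filtered, -dm, -dn) if (dm or dn) else filtered
            )
        else:
            offsets.append((0, 0))
            informative.append([False] * stab_grid.n_regions)
            region_list.append([(np.nan, np.nan)] * stab_grid.n_regions)
            stabilized = filtered
        mask = _channel_masks(stabilized, config.thresholds)
        s, c = region_sums(stabilized, mask, bounds, ci)
        sums.append(s)
        counts.append(c)

    if not sums:
        raise ValueError("the input contains no frames")

    sums = np.array(sums).T  # (R, I)
    cnt = np.array(counts).T
    if config.strict_area_denominator:
        areas = np.array([(r1 - r0) * (c1 - c0) for r0, r1, c0, c1 in bounds])
        traces_arr = sums / areas[:, None]
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            traces_arr = sums / cnt
    region_signal = RegionSignal(
        traces_arr, cnt, fps, sig_grid, config.min_skin_pixels,
        config.channel.upper(),
    )
    stab_result = StabilizationResult(
        np.array(offsets, int),
        np.array(region_list, float),
        np.array(informative, bool),
        config.max_shift,
        stab_grid,
    )
    traces = pulse_trace(region_signal, config.pulse)
    return PipelineResult(traces, region_signal, stab_result, config, fps)
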