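"""Reference measurement scenarios for the limitation experiments.

These functions pin down the package's standard desk-scale study
conditions — one reference scene and its resolution / frame-rate /
lighting variants — and measure the pipeline's absolute pulse error δ on
them.  The same scenarios back the acceptance checks and the worked
examples, so the numbers they produce are reproducible from a seed alone.

The reference scene is the :class:`~pulsecam.synthetic.SceneConfig`
default geometry (240×320 px, ≈41,000-pixel skin ellipse, pulse
72 beats/min, 3 % red modulation, sensor noise σ = 0.005, ±2 px jitter,
daylight) recorded for 60 s at 30 frames/s.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .evaluation import scene_error
from .pipeline import PipelineConfig
from .synthetic import FLICKER_PRESETS, SceneConfig, scene_ground_truth

__all__ = [
    "reference_scene",
    "pooled_scene_errors",
    "error_at_pixel_count",
    "error_at_fps",
    "error_with_flicker",
]


def reference_scene(seed, **overrides) -> SceneConfig:
    """The 60-second reference recording with the given seed."""
    return replace(SceneConfig(duration_s=60.0, seed=seed), **overrides)


def _measure(config: SceneConfig, **kwargs) -> np.ndarray:
    """Per-reading absolute errors |estimate − truth| of one scene."""
    rec = scene_error(config, return_deltas=True, **kwargs)
    return rec["deltas"]


def pooled_scene_errors(
    configs, pipeline_config: PipelineConfig | None = None, **kwargs
) -> dict:
    """Pool significant-reading errors over several seeded scenes."""
    deltas = [
        _measure(cfg, pipeline_config=pipeline_config, **kwargs)
        for cfg in configs
    ]
    pooled = np.concatenate(deltas) if deltas else np.empty(0)
    return {
        "median_delta": float(np.median(pooled)) if pooled.size else float("nan"),
        "n_significant": int(pooled.size),
        "n_scenes": len(configs),
    }


def error_at_pixel_count(
    pixel_count: int | None,
    seeds,
    noise_sigma: float | None = None,
    duration_s: float = 60.0,
) -> dict:
    """Median δ with the reference scene downscaled to ``pixel_count``
    skin pixels (optionally with a different sensor-noise level).

    ``pixel_count=None`` analyses the reference resolution unchanged
    (≈41,000 skin pixels).
    """
    base = reference_scene(0, duration_s=duration_s)
    base_count = scene_ground_truth(base).skin_pixel_count
    if pixel_count is None or pixel_count >= base_count:
        scale, shape = 1.0, tuple(base.shape)
    else:
        scale = np.sqrt(pixel_count / base_count)
        shape = (
            max(int(round(base.shape[0] * scale)), 2),
            max(int(round(base.shape[1] * scale)), 2),
        )
    overrides = {"duration_s": duration_s}
    if noise_sigma is not None:
        overrides["noise_sigma"] = noise_sigma
    configs = [reference_scene(s, **overrides) for s in seeds]
    out = pooled_scene_errors(configs, shape=shape if scale < 1.0 else None)
    out["pixel_count_target"] = pixel_count if pixel_count is not None else base_count
    out["analysed_shape"] = shape
    return out


def error_at_fps(
    fps: float, seeds, duration_s: float = 120.0
) -> dict:
    """Median δ at a reduced camera frame rate (nearest-frame decimation
    of the 30 frames/s reference scene)."""
    configs = [reference_scene(s, duration_s=duration_s) for s in seeds]
    base_fps = configs[0].fps
    out = pooled_scene_errors(
        configs, target_fps=fps if fps != base_fps else None
    )
    out["fps"] = fps
    return out


def error_with_flicker(
    flicker: str, seeds, duration_s: float = 60.0
) -> dict:
    """Median δ with a lighting-flicker model applied to the reference
    scene."""
    configs = [
        reference_scene(s, duration_s=duration_s, flicker=FLICKER_PRESETS[flicker])
        for s in seeds
    ]
    out = pooled_scene_errors(configs)
    out["flicker"] = flicker
    return out
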