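"""Accuracy metrics and the limitation-sweep runners.

Two agreement tools mirror how camera pulse readings are scored against a
contact reference (a pulse oximeter, or here the simulator's ground truth):

* the per-frame error δ = |estimate − reference| in beats/min, summarized
  by its median and maximum over statistically significant frames;
* Bland–Altman limits of agreement: mean difference ± 1.96 times the
  sample standard deviation of the paired differences.

The sweep runners re-run the full pipeline on families of synthetic scenes
to map how accuracy degrades with spatial resolution (skin-pixel count) and
camera frame rate; every cell records its seed and replicate count, so a
report is reproducible from its metadata alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pipeline import PipelineConfig, run_pipeline
from .synthetic import SceneConfig, iter_scene_frames, scene_ground_truth
from .video_io import decimation_indices, downscale_frame

__all__ = [
    "AgreementResult",
    "DeltaSummary",
    "SweepReport",
    "delta_error",
    "bland_altman",
    "scene_error",
    "sweep_resolution",
    "sweep_fps",
]


@dataclass
class DeltaSummary:
    """Per-frame absolute error δ and its summaries over significant frames."""

    per_frame: np.ndarray  # (I,) |estimate − reference|, NaN where insignificant
    median: float
    max: float
    n_significant: int

    @property
    def measurable(self) -> bool:
        return self.n_significant > 0


def delta_error(estimate, reference) -> DeltaSummary:
    """Absolute pulse error δ = |estimate − reference| per frame.

    ``estimate`` is a pulse trace with NaN at insignificant frames;
    ``reference`` is a scalar or an aligned trace.  Insignificant frames
    are excluded from the summaries; with no significant frame at all the
    summary is unmeasurable (NaN median/max).
    """
    est = np.asarray(estimate, float)
    ref = np.asarray(reference, float)
    if ref.ndim == 0:
        ref = np.full_like(est, float(ref))
    if est.shape != ref.shape:
        raise ValueError(
            f"traces are not aligned: {est.shape} vs {ref.shape}"
        )
    delta = np.abs(est - ref)
    valid = np.isfinite(delta)
    if valid.any():
        return DeltaSummary(
            delta, float(np.median(delta[valid])), float(delta[valid].max()),
            int(valid.sum()),
        )
    return DeltaSummary(delta, float("nan"), float("nan"), 0)


@dataclass
class AgreementResult:
    """Bland–Altman agreement between two paired measurement series."""

    differences: np.ndarray  # method − reference per pair
    means: np.ndarray  # pairwise means
    mean_difference: float
    sd: float  # sample standard deviation of the differences
    limit_lower: float  # mean − 1.96·sd
    limit_upper: float  # mean + 1.96·sd
    inside_fraction: float

    @property
    def n(self) -> int:
        return self.differences.size


def bland_altman(method_values, reference_values) -> AgreementResult:
    """Bland–Altman limits of agreement for paired pulse readings.

    Differences and pairwise means, the mean difference, the sample
    standard deviation σ of the differences (n−1 denominator), the limits
    mean ± 1.96σ, and the fraction of pairs falling inside the limits.
    """
    a = np.asarray(method_values, float)
    b = np.asarray(reference_values, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"need two equal-length 1-D series, got {a.shape} and {b.shape}"
        )
    if a.size < 2:
        raise ValueError("Bland–Altman analysis needs at least 2 pairs")
    d = a - b
    m = (a + b) / 2.0
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean_d - 1.96 * sd, mean_d + 1.96 * sd
    inside = float(((d >= lo) & (d <= hi)).mean())
    return AgreementResult(d, m, mean_d, sd, lo, hi, inside)


# ---------------------------------------------------------------------------
# sweep runners
# ---------------------------------------------------------------------------


@dataclass
class SweepReport:
    """Grid of conditions × error δ with full reproducibility metadata."""

    kind: str
    table: pd.DataFrame  # one row per (cell, replicate)
    metadata: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Median δ (and measurement status) per condition cell."""
        keys = [c for c in self.table.columns if c.startswith("cond_")]
        grouped = self.table.groupby(keys, dropna=False)
        out = grouped.agg(
            median_delta=("median_delta", "median"),
            n_replicates=("replicate", "count"),
            n_measured=("measurable", "sum"),
        ).reset_index()
        out["status"] = np.where(
            out["n_measured"] > 0, "measured", "no measurement"
        )
        if "status_note" in self.table.columns:
            notes = grouped["status_note"].first().reset_index(drop=True)
            out.loc[notes.notna().to_numpy(), "status"] = notes.dropna().to_numpy()
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self) -> str:
        """Human-readable table mirroring the published result layout."""
        s = self.summary()
        lines = [f"{self.kind} sweep ({self.metadata})", ""]
        header = " | ".join(f"{c:>16}" for c in s.columns)
        lines += [header, "-" * len(header)]
        for _, row in s.iterrows():
            lines.append(
                " | ".join(
                    f"{v:16.2f}" if isinstance(v, float) else f"{str(v):>16}"
                    for v in row
                )
            )
        return "\n".join(lines)


def _requantize(frame: np.ndarray) -> np.ndarray:
    frame *= 255.0
    np.rint(frame, out=frame)
    frame /= 255.0
    return frame


def _stream(config: SceneConfig, shape=None, target_fps=None):
    """Scene frames, optionally downscaled and/or temporally decimated.

    Downscaled frames are requantized to 256 brightness levels: a camera
    delivering the lower resolution would still output 8-bit values.
    """
    it = iter_scene_frames(config)
    if target_fps is not None and target_fps != config.fps:
        keep = set(
            decimation_indices(config.n_frames, config.fps, target_fps).tolist()
        )
        it = (f for i, f in enumerate(it) if i in keep)
    if shape is not None and tuple(shape) != tuple(config.shape):
        it = (downscale_frame(f, shape[0], shape[1]) for f in it)
        if config.quantize:
            it = (_requantize(f) for f in it)
    return it


def scene_error(
    config: SceneConfig,
    pipeline_config: PipelineConfig | None = None,
    shape: tuple[int, int] | None = None,
    target_fps: float | None = None,
    true_bpm: float | None = None,
    return_deltas: bool = False,
) -> dict:
    """Run the full pipeline on one synthetic scene and score it.

    The scene is streamed (optionally downscaled to ``shape`` and/or
    decimated to ``target_fps``) through the pipeline and the significant
    pulse readings of all measurable regions are pooled against the ground
    truth.  Returns a record with the median/max δ, counts, and the scene's
    true skin-pixel count at the analysed resolution.
    """
    pipeline_config = pipeline_config or PipelineConfig()
    truth = scene_ground_truth(config)
    fps = target_fps if target_fps is not None else config.fps
    result = run_pipeline(_stream(config, shape, target_fps), fps, pipeline_config)
    bpm_true = true_bpm if true_bpm is not None else float(config.pulse_bpm)
    pooled = result.pooled_significant()
    deltas = np.abs(pooled - bpm_true)
    n_windows = sum(
        int(np.isfinite(t.bpm).size) for t in result.traces
    )
    if shape is not None and tuple(shape) != tuple(config.shape):
        sr, sc = shape[0] / config.shape[0], shape[1] / config.shape[1]
        if config.skin_ellipse is not None:
            cy, cx, ay, ax = config.skin_ellipse
            yy, xx = np.ogrid[: shape[0], : shape[1]]
            skin_pixels = int(
                (((yy - cy * sr) / (ay * sr)) ** 2
                 + ((xx - cx * sc) / (ax * sc)) ** 2 <= 1.0).sum()
            )
        else:
            skin_pixels = shape[0] * shape[1]
    else:
        skin_pixels = truth.skin_pixel_count
    out = {
        "median_delta": float(np.median(deltas)) if deltas.size else float("nan"),
        "max_delta": float(deltas.max()) if deltas.size else float("nan"),
        "n_significant": int(deltas.size),
        "measurable": bool(deltas.size),
        "skin_pixels": skin_pixels,
        "n_regions_measurable": int(result.measurable_regions.sum()),
    }
    if return_deltas:
        out["deltas"] = deltas
    return out


def _cell_seed(seed: int, cell: int, rep: int) -> list[int]:
    return [int(seed), cell, rep]


def sweep_resolution(
    base_scene: SceneConfig,
    pixel_counts,
    replicates: int = 3,
    seed: int = 0,
    pipeline_config: PipelineConfig | None = None,
) -> SweepReport:
    """Error δ as a function of the skin-pixel count (spatial resolution).

    For each target pixel count the base scene is downscaled isotropically
    until its true skin mask holds approximately that many pixels, then the
    full pipeline runs on ``replicates`` seeded scenes.  Cells whose skin
    area falls below the measurable minimum are reported as
    "no measurement".
    """
    base_cfg = replace(base_scene, seed=0)
    base_count = scene_ground_truth(base_cfg).skin_pixel_count
    rows = []
    for ci, target in enumerate(pixel_counts):
        scale = min(np.sqrt(target / base_count), 1.0)
        shape = (
            max(int(round(base_scene.shape[0] * scale)), 2),
            max(int(round(base_scene.shape[1] * scale)), 2),
        )
        for rep in range(replicates):
            cfg = replace(base_scene, seed=_cell_seed(seed, ci, rep))
            rec = scene_error(cfg, pipeline_config, shape=shape)
            rec.update(
                cond_pixel_count=target,
                replicate=rep,
                seed=str(cfg.seed),
                analysed_shape=f"{shape[0]}x{shape[1]}",
            )
            rows.append(rec)
    return SweepReport(
        "resolution",
        pd.DataFrame(rows),
        {
            "base_skin_pixels": base_count,
            "replicates": replicates,
            "seed": seed,
            "true_pulse_bpm": base_scene.pulse_bpm,
        },
    )


def sweep_fps(
    base_scene: SceneConfig,
    fps_list,
    pulse_list=None,
    replicates: int = 3,
    seed: int = 0,
    pipeline_config: PipelineConfig | None = None,
) -> SweepReport:
    """Error δ over camera frame rate × true pulse frequency.

    Scenes are rendered at the base frame rate and decimated to each target
    rate.  Cells where the pulse frequency reaches the Nyquist limit of the
    frame rate are reported as "aliased" and not run.
    """
    pulse_list = list(pulse_list) if pulse_list is not None else [base_scene.pulse_bpm]
    rows = []
    for pj, pulse in enumerate(pulse_list):
        for fi, fps in enumerate(fps_list):
            cell = pj * len(fps_list) + fi
            aliased = pulse / 60.0 >= fps / 2.0
            for rep in range(replicates):
                cfg = replace(
                    base_scene, pulse_bpm=pulse, seed=_cell_seed(seed, cell, rep)
                )
                if aliased:
                    rec = {
                        "median_delta": float("nan"),
                        "max_delta": float("nan"),
                        "n_significant": 0,
                        "measurable": False,
                        "skin_pixels": scene_ground_truth(cfg).skin_pixel_count,
                        "n_regions_measurable": 0,
                        "status_note": "aliased",
                    }
                else:
                    rec = scene_error(cfg, pipeline_config, target_fps=fps)
                    rec["status_note"] = None
                rec.update(
                    cond_fps=fps,
                    cond_pulse_bpm=pulse,
                    replicate=rep,
                    seed=str(cfg.seed),
                )
                rows.append(rec)
    return SweepReport(
        "frame-rate",
        pd.DataFrame(rows),
        {"replicates": replicates, "seed": seed, "base_fps": base_scene.fps},
    )
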