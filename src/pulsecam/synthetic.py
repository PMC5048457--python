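"""Ground-truthed synthetic facial-video scenes.

The simulator emulates the statistical structure the measurement pipeline
assumes about a webcam recording of a face:

* an elliptical skin-coloured patch whose red channel oscillates at the
  ground-truth pulse frequency (multiplicative modulation of a base colour
  lying inside the skin segmentation ranges);
* a static speckle texture on the patch so edge detection and shift
  correlation have structure to lock onto;
* sensor-noise clusters of at most 4 pixels (the impulse noise the 9×9
  median filter exists for), per-pixel Gaussian sensor noise, and 8-bit
  quantization as in a real camera;
* global frame jitter as an integer random walk, clamped to the ±10 px
  stabilization search range;
* multiplicative lighting flicker at twice the mains frequency (100 Hz)
  for LED / fluorescent / incandescent sources, constant for daylight.

Every scene is deterministic given its seed — the random draws happen in a
fixed order (textures, jitter path, then per-frame noise), so streaming the
frames and rendering them in batch produce bit-identical sequences — and
comes with a :class:`GroundTruth` record (true pulse, jitter path, skin
mask) so the pipeline's output can be scored without a contact reference
device.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

from .errors import ConfigurationError
from .preprocess import RegionGrid, translate_frame
from .segmentation import CAUCASIAN_THRESHOLDS, SIGNAL_GRID_SHAPE, ChannelThresholds
from .video_io import FrameSequence

__all__ = [
    "FlickerModel",
    "FLICKER_PRESETS",
    "SceneConfig",
    "GroundTruth",
    "flicker_waveform",
    "generate_scene",
    "iter_scene_frames",
    "multi_person_scene",
]


@dataclass(frozen=True)
class FlickerModel:
    """Multiplicative lighting ripple: ``1 + depth·sin(2π f t)``.

    ``envelope_hz``/``envelope_depth`` slowly modulate the ripple depth,
    emulating half-powered LED drivers whose ripple amplitude wanders.
    Depth 0 is steady (daylight) illumination.
    """

    name: str = "daylight"
    frequency_hz: float = 100.0  # twice the 50 Hz mains frequency
    depth: float = 0.0
    envelope_hz: float = 0.0
    envelope_depth: float = 0.0


#: Ripple presets per lighting type (European 50 Hz mains, 100 Hz ripple).
FLICKER_PRESETS: dict[str, FlickerModel] = {
    "daylight": FlickerModel("daylight", depth=0.0),
    "led": FlickerModel("led", 100.0, 0.05),
    "led_half_power": FlickerModel("led_half_power", 100.0, 0.05, 1.3, 0.5),
    "fluorescent": FlickerModel("fluorescent", 100.0, 0.10),
    "incandescent": FlickerModel("incandescent", 100.0, 0.005),
}


def flicker_waveform(model: FlickerModel | str, t) -> np.ndarray:
    """Multiplicative illumination factor at time(s) ``t`` (seconds)."""
    if isinstance(model, str):
        try:
            model = FLICKER_PRESETS[model]
        except KeyError:
            raise ConfigurationError(
                f"unknown flicker preset {model!r}; "
                f"choose from {sorted(FLICKER_PRESETS)}"
            ) from None
    t = np.asarray(t, dtype=float)
    depth = model.depth
    if model.envelope_depth:
        depth = depth * (
            1.0 + model.envelope_depth * np.sin(2 * np.pi * model.envelope_hz * t)
        )
    return 1.0 + depth * np.sin(2 * np.pi * model.frequency_hz * t)


def _pulse_waveform(theta, kind: str):
    """Unit-amplitude periodic pulse waveform w(θ)."""
    if kind == "sinusoid":
        return np.sin(theta)
    if kind == "pulse":  # asymmetric systolic-peak shape, max |w| = 1
        w = np.sin(theta) + 0.35 * np.sin(2 * np.asarray(theta))
        return w / 1.2425  # numerical max of the two-harmonic shape
    raise ConfigurationError(f"unknown waveform {kind!r}")


@dataclass(frozen=True)
class SceneConfig:
    """Complete description of one synthetic recording.

    The skin ellipse is ``(centre_row, centre_col, semi_axis_rows,
    semi_axis_cols)`` in pixels; ``None`` fills the whole frame with skin.
    ``base_color`` must lie inside the segmentation thresholds unless the
    scene is deliberately adversarial (``allow_adversarial=True``).
    Modulation multiplies the red channel:
    ``R(t) = base_R · (1 + A·w(2π f t)) · flicker(t)``.

    The defaults describe the reference desk-scale scene: a 240×320 px
    frame at 30 frames/s whose 100×130 px-semi-axis ellipse holds ≈41,000
    skin pixels, pulse 72 beats/min with 3 % red modulation, sensor noise
    σ = 0.005, ±2 px jitter steps, daylight lighting.
    """

    shape: tuple[int, int] = (240, 320)
    fps: float = 30.0
    duration_s: float = 30.0
    skin_ellipse: tuple[float, float, float, float] | None = (120, 160, 100, 130)
    base_color: tuple[float, float, float] = (0.68, 0.55, 0.55)
    pulse_bpm: float = 72.0
    modulation_amplitude: float = 0.03
    waveform: str = "sinusoid"
    noise_sigma: float = 0.005
    cluster_noise_per_frame: int = 5
    jitter_max_step: int = 1
    jitter_clamp: int = 2
    flicker: FlickerModel = FLICKER_PRESETS["daylight"]
    texture_sigma: float = 0.015
    texture_clip: float = 0.04
    background_color: tuple[float, float, float] = (0.2, 0.3, 0.9)
    quantize: bool = True
    allow_adversarial: bool = False
    thresholds: ChannelThresholds = CAUCASIAN_THRESHOLDS
    seed: int | Sequence[int] = 0

    @property
    def n_frames(self) -> int:
        return max(int(round(self.duration_s * self.fps)), 1)

    def validate(self) -> None:
        M, N = self.shape
        if M < 2 or N < 2:
            raise ConfigurationError(f"frame shape too small: {self.shape}")
        if not self.fps > 0:
            raise ConfigurationError(f"fps must be positive, got {self.fps}")
        if not 0.0 <= self.modulation_amplitude < 1.0:
            raise ConfigurationError(
                "modulation amplitude must be in [0, 1), got "
                f"{self.modulation_amplitude}"
            )
        if self.jitter_clamp > 10:
            raise ConfigurationError(
                "jitter_clamp may not exceed the ±10 px stabilization bound"
            )
        if abs(self.jitter_max_step) > self.jitter_clamp:
            raise ConfigurationError("jitter_max_step exceeds jitter_clamp")
        if not self.allow_adversarial and not self.thresholds.contains(
            self.base_color
        ):
            raise ConfigurationError(
                f"base colour {self.base_color} lies outside the skin "
                "segmentation thresholds; set allow_adversarial=True if "
                "intended"
            )


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline must recover."""

    pulse_bpm: np.ndarray  # (I,) true pulse per frame (NaN where no pulse)
    jitter: np.ndarray  # (I, 2) applied integer (dm, dn) per frame
    mask: np.ndarray  # (M, N) true skin mask in reference (frame-1) coords
    fps: float
    region_bpm: np.ndarray | None = None  # (R,) for multi-person scenes

    @property
    def skin_pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class _SkinPatch:
    """One pulsatile patch: geometry plus its modulation parameters."""

    mask: np.ndarray  # (M, N) bool
    base_color: tuple[float, float, float]
    pulse_bpm: float
    amplitude: float
    waveform: str
    texture: np.ndarray | None = None  # (n_skin, 3), drawn at render time


def _ellipse_mask(shape: tuple[int, int], ellipse) -> np.ndarray:
    M, N = shape
    if ellipse is None:
        return np.ones((M, N), bool)
    cy, cx, ay, ax = ellipse
    yy, xx = np.ogrid[:M, :N]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _jitter_path(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    I = config.n_frames
    path = np.zeros((I, 2), int)
    if config.jitter_max_step > 0 and I > 1:
        steps = rng.integers(
            -config.jitter_max_step, config.jitter_max_step + 1, size=(I - 1, 2)
        )
        walk = np.cumsum(steps, axis=0)
        path[1:] = np.clip(walk, -config.jitter_clamp, config.jitter_clamp)
    return path


def _static_draws(
    config: SceneConfig, patches: list[_SkinPatch]
) -> tuple[np.random.Generator, np.ndarray]:
    """Draw the per-scene randomness (textures, jitter) in a fixed order."""
    rng = np.random.default_rng(config.seed)
    for p in patches:
        tex = rng.normal(0.0, config.texture_sigma, (int(p.mask.sum()), 3))
        np.clip(tex, -config.texture_clip, config.texture_clip, out=tex)
        p.texture = tex.astype(np.float32)
    jitter = _jitter_path(config, rng)
    return rng, jitter


def _frame_iter(
    config: SceneConfig,
    patches: list[_SkinPatch],
    jitter: np.ndarray,
    rng: np.random.Generator,
) -> Iterator[np.ndarray]:
    M, N = config.shape
    base = np.empty((M, N, 3), np.float32)
    base[:] = np.asarray(config.background_color, np.float32)
    for p in patches:
        base[p.mask] = np.asarray(p.base_color, np.float32) + p.texture
    for i in range(config.n_frames):
        t = i / config.fps
        flick = float(flicker_waveform(config.flicker, t))
        frame = base * flick
        for p in patches:
            if p.amplitude:
                mod = 1.0 + p.amplitude * float(
                    _pulse_waveform(2 * np.pi * p.pulse_bpm / 60.0 * t, p.waveform)
                )
                frame[p.mask, 0] = (p.base_color[0] + p.texture[:, 0]) * mod * flick
        dm, dn = int(jitter[i, 0]), int(jitter[i, 1])
        if dm or dn:
            frame = translate_frame(frame, dm, dn)
        if config.cluster_noise_per_frame > 0:
            rows = rng.integers(0, M - 1, config.cluster_noise_per_frame)
            cols = rng.integers(0, N - 1, config.cluster_noise_per_frame)
            sizes = rng.integers(1, 3, (config.cluster_noise_per_frame, 2))
            bright = rng.random(config.cluster_noise_per_frame) < 0.5
            for r, c, (sr, sc), v in zip(rows, cols, sizes, bright):
                frame[r : r + sr, c : c + sc] = 1.0 if v else 0.0
        if config.noise_sigma > 0:
            noise = rng.standard_normal(frame.shape, dtype=np.float32)
            noise *= config.noise_sigma
            frame += noise
        np.clip(frame, 0.0, 1.0, out=frame)
        if config.quantize:
            frame *= 255.0
            np.rint(frame, out=frame)
            frame /= 255.0
        yield frame


def _single_patch(config: SceneConfig) -> list[_SkinPatch]:
    mask = _ellipse_mask(config.shape, config.skin_ellipse)
    return [
        _SkinPatch(
            mask,
            config.base_color,
            config.pulse_bpm,
            config.modulation_amplitude,
            config.waveform,
        )
    ]


def iter_scene_frames(config: SceneConfig) -> Iterator[np.ndarray]:
    """Stream the scene's frames one at a time (constant memory)."""
    config.validate()
    patches = _single_patch(config)
    rng, jitter = _static_draws(config, patches)
    return _frame_iter(config, patches, jitter, rng)


def scene_ground_truth(config: SceneConfig) -> GroundTruth:
    """Ground truth of :func:`iter_scene_frames` without rendering frames."""
    config.validate()
    patches = _single_patch(config)
    _, jitter = _static_draws(config, patches)
    pulse = np.full(
        config.n_frames,
        config.pulse_bpm if config.modulation_amplitude > 0 else np.nan,
    )
    return GroundTruth(pulse, jitter, patches[0].mask, config.fps)


def generate_scene(config: SceneConfig) -> tuple[FrameSequence, GroundTruth]:
    """Render the full scene into memory together with its ground truth.

    Deterministic given ``config.seed``; the red channel of skin pixels is
    ``base_R · (1 + A·w(2π f t)) · flicker(t)`` plus speckle texture and
    sensor noise, the background colour lies outside all segmentation
    ranges, and jitter is applied as a global integer translation.
    """
    seq = FrameSequence.from_frames(list(iter_scene_frames(config)), config.fps)
    return seq, scene_ground_truth(config)


def multi_person_scene(
    configs: Sequence[SceneConfig | None],
    grid: RegionGrid | None = None,
) -> tuple[FrameSequence, GroundTruth]:
    """Scene with one independent pulsatile skin patch per grid region.

    ``configs[r]`` describes region ``r``'s patch (its ``pulse_bpm``,
    ``base_color``, ``modulation_amplitude``, ``waveform``); ``None``
    leaves the region empty.  Global settings (shape, fps, duration,
    jitter, flicker, noise, seed) come from the first non-None config.
    Patches are ellipses inscribed in their region at 80 % scale;
    per-region frequencies are recorded in ``GroundTruth.region_bpm``.
    """
    grid = grid or RegionGrid(*SIGNAL_GRID_SHAPE)
    if len(configs) > grid.n_regions:
        raise ConfigurationError(
            f"{len(configs)} patch configs for {grid.n_regions} regions"
        )
    anchor = next((c for c in configs if c is not None), None)
    if anchor is None:
        raise ConfigurationError("at least one region config is required")
    scene_cfg = replace(anchor, skin_ellipse=None)
    scene_cfg.validate()
    M, N = scene_cfg.shape
    bounds = grid.bounds(M, N)
    patches = []
    region_bpm = np.full(grid.n_regions, np.nan)
    for r, cfg in enumerate(configs):
        if cfg is None:
            continue
        r0, r1, c0, c1 = bounds[r]
        ell = (
            (r0 + r1) / 2.0,
            (c0 + c1) / 2.0,
            0.4 * (r1 - r0),
            0.4 * (c1 - c0),
        )
        patches.append(
            _SkinPatch(
                _ellipse_mask((M, N), ell),
                cfg.base_color,
                cfg.pulse_bpm,
                cfg.modulation_amplitude,
                cfg.waveform,
            )
        )
        if cfg.modulation_amplitude > 0:
            region_bpm[r] = cfg.pulse_bpm
    rng, jitter = _static_draws(scene_cfg, patches)
    frames = list(_frame_iter(scene_cfg, patches, jitter, rng))
    seq = FrameSequence.from_frames(frames, scene_cfg.fps)
    mask_all = np.zeros((M, N), bool)
    for p in patches:
        mask_all |= p.mask
    truth = GroundTruth(
        np.full(scene_cfg.n_frames, np.nan),
        jitter,
        mask_all,
        scene_cfg.fps,
        region_bpm=region_bpm,
    )
    return seq, truth
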