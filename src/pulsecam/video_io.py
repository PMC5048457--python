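"""Reading, writing and resampling of colour frame sequences.

A recording is held as a :class:`FrameSequence`: a 4-D brightness array
indexed ``(row, column, channel, frame)`` with values in ``[0, 1]`` plus the
camera frame rate.  Consumer cameras deliver 256 brightness levels per RGB
component, so 8-bit PNG is the canonical on-disk dialect; ``write_sequence``
quantizes to 8 bits and a read/write round trip is lossless up to 1/255.

Spatial and temporal resampling exist for the resolution / frame-rate
limitation sweeps and therefore only shrink: downscaling is area-averaged
(anti-aliased) and frame-rate reduction selects nearest-in-time frames.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ConfigurationError, ShapeMismatchError

__all__ = [
    "FrameSequence",
    "read_sequence",
    "write_sequence",
    "resample_spatial",
    "resample_temporal",
    "downscale_frame",
    "decimation_indices",
]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp"}
FRAME_NAME_FORMAT = "frame_%05d.png"


@dataclass
class FrameSequence:
    """Colour video clip: brightness array ``(M, N, 3, I)`` plus frame rate.

    Attributes
    ----------
    frames:
        Brightness in ``[0, 1]``, indexed ``(row m, column n, channel s, frame i)``
        with ``s`` running over R, G, B.
    fps:
        Frames per second, > 0.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[2] != 3:
            raise ShapeMismatchError(
                f"frames must have shape (M, N, 3, I), got {self.frames.shape}"
            )
        if self.frames.shape[3] < 1:
            raise ConfigurationError("a sequence needs at least one frame")
        if not self.fps > 0:
            raise ConfigurationError(f"fps must be positive, got {self.fps}")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < 0.0 or hi > 1.0:
            raise ConfigurationError(
                f"brightness must lie in [0, 1], found range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """Frame shape ``(M rows, N columns)``."""
        return self.frames.shape[0], self.frames.shape[1]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[3]

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.n_frames / self.fps

    def frame(self, i: int) -> np.ndarray:
        """Return frame ``i`` as an ``(M, N, 3)`` array (contiguous copy)."""
        return np.ascontiguousarray(self.frames[:, :, :, i])

    def iter_frames(self):
        """Yield frames as ``(M, N, 3)`` arrays in temporal order."""
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_frames(cls, frames: list[np.ndarray], fps: float) -> "FrameSequence":
        """Stack a list of ``(M, N, 3)`` frames into a sequence."""
        return cls(np.stack(frames, axis=-1), fps)


def _to_unit_float(img: np.ndarray, origin: str) -> np.ndarray:
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise ShapeMismatchError(
            f"{origin}: expected an RGB image, got shape {img.shape}"
        )
    if img.dtype == np.uint8:
        return img.astype(np.float32) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float32) / 65535.0
    out = img.astype(np.float32)
    if out.min() < 0.0 or out.max() > 1.0:
        raise ConfigurationError(
            f"{origin}: float image values must lie in [0, 1]"
        )
    return out


def _numbered_image_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in _IMAGE_SUFFIXES and re.search(r"\d", p.stem)
    )
    return files


def read_sequence(path, fps_override: float | None = None) -> FrameSequence:
    """Read a video container or a directory of numbered image frames.

    Parameters
    ----------
    path:
        Video file decodable by :mod:`imageio`, or a directory of numbered
        PNG/JPEG/BMP frames (lexicographic order = temporal order).
    fps_override:
        Frame rate to assign.  Required for directory input; for container
        input it overrides the container metadata.

    Integer-encoded inputs are rescaled to ``[0, 1]`` (8-bit: divided by 255).
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"input path does not exist: {path}")
    if path.is_dir():
        if fps_override is None:
            raise ConfigurationError(
                f"fps_override is required for directory input: {path}"
            )
        files = _numbered_image_files(path)
        if not files:
            raise OSError(f"no numbered image frames found in directory: {path}")
        frames = []
        for f in files:
            try:
                img = iio.imread(f)
            except Exception as exc:  # noqa: BLE001 - decoder errors vary
                raise OSError(f"could not read image frame {f}: {exc}") from exc
            frames.append(_to_unit_float(img, str(f)))
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ShapeMismatchError(
                f"frames in {path} have mixed shapes: {sorted(shapes)}"
            )
        return FrameSequence.from_frames(frames, float(fps_override))

    # single file: video container
    try:
        raw = iio.imread(path)
        meta = iio.immeta(path)
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"could not decode video file {path}: {exc}") from exc
    fps = fps_override if fps_override is not None else meta.get("fps")
    if fps is None:
        raise ConfigurationError(
            f"container {path} carries no frame rate; pass fps_override"
        )
    if raw.ndim == 3:  # single frame
        raw = raw[None]
    frames = [_to_unit_float(fr, str(path)) for fr in raw]
    return FrameSequence.from_frames(frames, float(fps))


def write_sequence(seq: FrameSequence, path) -> list[Path]:
    """Write a sequence as zero-padded 8-bit PNG frames ``frame_%05d.png``.

    The destination directory is created if absent.  Returns the written
    file paths in frame order.
    """
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {path}: {exc}") from exc
    written = []
    for i in range(seq.n_frames):
        img = np.round(seq.frame(i) * 255.0).astype(np.uint8)
        target = path / (FRAME_NAME_FORMAT % i)
        try:
            iio.imwrite(target, img)
        except OSError as exc:
            raise OSError(f"cannot write frame {target}: {exc}") from exc
        written.append(target)
    return written


_AREA_WEIGHT_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _area_weights(src: int, dst: int) -> np.ndarray:
    """Row-overlap weight matrix ``(dst, src)`` for exact area averaging.

    Output cell ``r`` covers the source interval ``[r·src/dst, (r+1)·src/dst)``
    and weights each source cell by its fractional overlap; rows sum to 1.
    For integer ratios this reduces to a uniform block mean.
    """
    key = (src, dst)
    if key not in _AREA_WEIGHT_CACHE:
        step = src / dst
        w = np.zeros((dst, src), np.float32)
        for r in range(dst):
            lo, hi = r * step, (r + 1) * step
            i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
            for i in range(i0, min(i1, src)):
                w[r, i] = min(hi, i + 1) - max(lo, i)
        w /= w.sum(axis=1, keepdims=True)
        _AREA_WEIGHT_CACHE[key] = w
    return _AREA_WEIGHT_CACHE[key]


def downscale_frame(
    frame: np.ndarray, target_rows: int, target_cols: int
) -> np.ndarray:
    """Area-averaging (anti-aliased) downscaling of one ``(M, N, 3)`` frame.

    Every output pixel is the exact mean of the source area it covers, for
    integer and fractional ratios alike.
    """
    M, N = frame.shape[:2]
    if target_rows < 2 or target_cols < 2:
        raise ConfigurationError("target dimensions must be at least 2")
    if target_rows > M or target_cols > N:
        raise ConfigurationError(
            f"upscaling is not supported: {M}x{N} -> {target_rows}x{target_cols}"
        )
    if target_rows == M and target_cols == N:
        return frame.copy()
    wr = _area_weights(M, target_rows)
    wc = _area_weights(N, target_cols)
    f32 = np.ascontiguousarray(frame, np.float32)
    rows = (wr @ f32.reshape(M, N * 3)).reshape(target_rows, N, 3)
    cols = (wc @ rows.transpose(1, 0, 2).reshape(N, target_rows * 3)).reshape(
        target_cols, target_rows, 3
    )
    out = cols.transpose(1, 0, 2)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def resample_spatial(
    seq: FrameSequence, target_rows: int, target_cols: int
) -> FrameSequence:
    """Anti-aliased (area-averaging) downscaling of a whole sequence.

    Only shrinking is supported — the limitation sweeps never upscale.
    The frame rate is unchanged.
    """
    out = np.empty((target_rows, target_cols, 3, seq.n_frames), np.float32)
    for i in range(seq.n_frames):
        out[:, :, :, i] = downscale_frame(seq.frame(i), target_rows, target_cols)
    return FrameSequence(out, seq.fps)


def decimation_indices(n_frames: int, fps: float, target_fps: float) -> np.ndarray:
    """Frame indices kept when decimating ``fps`` to ``target_fps``
    (nearest-in-time selection)."""
    if not 0 < target_fps <= fps:
        raise ConfigurationError(
            f"target_fps must satisfy 0 < target_fps <= {fps}, got {target_fps}"
        )
    if target_fps == fps:
        return np.arange(n_frames)
    ratio = fps / target_fps
    n_out = int(np.ceil(n_frames / ratio))
    return np.minimum(np.round(np.arange(n_out) * ratio).astype(int), n_frames - 1)


def resample_temporal(seq: FrameSequence, target_fps: float) -> FrameSequence:
    """Reduce the frame rate by nearest-in-time frame selection.

    For an integer rate ratio ``k`` this keeps exactly every ``k``-th frame.
    Raising the frame rate is not supported.
    """
    idx = decimation_indices(seq.n_frames, seq.fps, target_fps)
    if target_fps == seq.fps:
        return FrameSequence(seq.frames.copy(), seq.fps)
    return FrameSequence(seq.frames[:, :, :, idx], float(target_fps))
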