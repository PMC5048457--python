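"""YAML (de)serialization of scene and pipeline configurations.

Every CLI run writes its fully resolved configuration next to its outputs,
so a result can be reproduced from the output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .pipeline import PipelineConfig
from .pulse_signal import PulseConfig
from .segmentation import ChannelThresholds
from .synthetic import FlickerModel, SceneConfig

__all__ = [
    "scene_config_to_dict",
    "scene_config_from_dict",
    "pipeline_config_to_dict",
    "pipeline_config_from_dict",
    "save_yaml",
    "load_scene_config",
    "load_pipeline_config",
    "config_hash",
]


def _plain(value):
    if isinstance(value, tuple):
        return [_plain(v) for v in value]
    return value


def scene_config_to_dict(config: SceneConfig) -> dict:
    d = dataclasses.asdict(config)
    d["flicker"] = dataclasses.asdict(config.flicker)
    d["thresholds"] = {
        "r": list(config.thresholds.r),
        "g": list(config.thresholds.g),
        "b": list(config.thresholds.b),
    }
    return {k: _plain(v) for k, v in d.items()}


def _tupled(d: dict, *keys) -> dict:
    out = dict(d)
    for k in keys:
        if out.get(k) is not None:
            out[k] = tuple(out[k])
    return out


def scene_config_from_dict(d: dict) -> SceneConfig:
    d = _tupled(
        dict(d), "shape", "skin_ellipse", "base_color", "background_color"
    )
    if "flicker" in d and isinstance(d["flicker"], dict):
        d["flicker"] = FlickerModel(**d["flicker"])
    elif isinstance(d.get("flicker"), str):
        from .synthetic import FLICKER_PRESETS

        d["flicker"] = FLICKER_PRESETS[d["flicker"]]
    if "thresholds" in d and isinstance(d["thresholds"], dict):
        t = d["thresholds"]
        d["thresholds"] = ChannelThresholds(
            tuple(t["r"]), tuple(t["g"]), tuple(t["b"])
        )
    try:
        return SceneConfig(**d)
    except TypeError as exc:
        raise ConfigurationError(f"bad scene configuration: {exc}") from exc


def pipeline_config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["thresholds"] = {
        "r": list(config.thresholds.r),
        "g": list(config.thresholds.g),
        "b": list(config.thresholds.b),
    }
    d["pulse"] = dataclasses.asdict(config.pulse)
    return {k: _plain(v) for k, v in d.items()}


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = _tupled(dict(d), "median_mask", "stabilization_grid", "signal_grid")
    if "thresholds" in d and isinstance(d["thresholds"], dict):
        t = d["thresholds"]
        d["thresholds"] = ChannelThresholds(
            tuple(t["r"]), tuple(t["g"]), tuple(t["b"])
        )
    if "pulse" in d and isinstance(d["pulse"], dict):
        d["pulse"] = PulseConfig(**d["pulse"])
    try:
        return PipelineConfig(**d)
    except TypeError as exc:
        raise ConfigurationError(f"bad pipeline configuration: {exc}") from exc


def save_yaml(data: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _load_yaml(path) -> dict:
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise OSError(f"cannot read configuration file {path}: {exc}") from exc
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    return data


def load_scene_config(path) -> SceneConfig:
    return scene_config_from_dict(_load_yaml(path))


def load_pipeline_config(path) -> PipelineConfig:
    return pipeline_config_from_dict(_load_yaml(path))


def config_hash(data: dict) -> str:
    """Short stable hash of a resolved configuration, for run logs."""
    text = yaml.safe_dump(data, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
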