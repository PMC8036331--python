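"""Run configuration: one validated, serialisable object drives the pipeline.

Every random operation reads a named seed; re-running with the same config
reproduces every artefact byte for byte. Unknown keys in a config file are an
error, never silently ignored.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    pass


@dataclass
class Seeds:
    vigour: int = 11
    scene: int = 22
    sampling: int = 33
    measurement: int = 44


@dataclass
class FieldConfig:
    plot_id: str = "A"
    variety: str = "Chardonnay"
    width_m: float = 22.0  # extent across rows
    length_m: float = 12.0  # extent along rows
    row_spacing: float = 2.2
    vine_spacing: float = 1.2
    row_azimuth: float = 0.0
    origin_x: float = 392_000.0
    origin_y: float = 4_588_000.0
    crs: str = "EPSG:25831"


@dataclass
class SceneConfig:
    gsd: float = 0.0648
    satellite_gsd: float = 3.0
    noise_sd: float = 0.01
    weed_patch_density: float = 20.0
    shadow_offset: float = 0.15
    margin: float = 5.0


@dataclass
class VigourConfig:
    base: float = 0.5
    trend_x: float = 0.006
    trend_y: float = 0.002
    n_bumps: int = 3
    bump_amplitude: float = 0.25
    bump_length_scale: float = 8.0
    noise_sd: float = 0.05
    h_min: float = 0.5
    h_max: float = 0.85
    w_min: float = 0.20
    w_max: float = 0.40


@dataclass
class SamplingConfig:
    row_period: int = 2
    vine_period: int = 2
    edge_buffer: float = 3.0


@dataclass
class MappingConfig:
    threshold: str | float = "auto"  # "auto" (Otsu) or a manual NDVI cut
    idw_power: float = 2.0
    idw_neighbours: int = 12


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    satellite_reject_edges: bool = True
    measurement_noise_sd: float = 0.02  # surveyor tape repeatability, m
    year: int = 2018
    make_plots: bool = True


@dataclass
class RunConfig:
    field: FieldConfig = dc_field(default_factory=FieldConfig)
    scene: SceneConfig = dc_field(default_factory=SceneConfig)
    vigour: VigourConfig = dc_field(default_factory=VigourConfig)
    sampling: SamplingConfig = dc_field(default_factory=SamplingConfig)
    mapping: MappingConfig = dc_field(default_factory=MappingConfig)
    analysis: AnalysisConfig = dc_field(default_factory=AnalysisConfig)
    seeds: Seeds = dc_field(default_factory=Seeds)
    stages: tuple[str, ...] = ("BBCH59", "BBCH75", "BBCH81")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


_SECTIONS = {
    "field": FieldConfig,
    "scene": SceneConfig,
    "vigour": VigourConfig,
    "sampling": SamplingConfig,
    "mapping": MappingConfig,
    "analysis": AnalysisConfig,
    "seeds": Seeds,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    stages = data.pop("stages", None)
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {
        name: _build_section(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    if stages is not None:
        kwargs["stages"] = tuple(stages)
    return RunConfig(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; ``None`` yields the default configuration."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 of the canonical JSON form (sidecar provenance)."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
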