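"""Nested pipeline configuration with YAML round-tripping.

Every tunable of the four pipeline stages, the metrics, and the
synthetic generator lives here with its study default.  Loading
validates types and value ranges and rejects unknown keys, so a config
file always describes exactly the resolved parameter set that a run
will log.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import ConfigError, DiffusionParams, PostprocessParams


@dataclass
class ImageConfig:
    px_scale_um: float = 0.899


@dataclass
class PreprocessConfig:
    nmf_seed: int = 0
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-4
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 0.01


@dataclass
class CEDConfig:
    tau: float = 1.0
    sigma: float = 1e-4
    rho: float = 4.0
    c1: float = 1e-10
    c2: float = 1e-3
    n_steps: int = 20


@dataclass
class PostprocessConfig:
    t_area: int = 750
    closing_radius: int = 4
    erosion_radius: int = 10


@dataclass
class MetricsConfig:
    encompass_frac: float = 0.5
    sliver_px: int = 5
    vc_scale: float = 1000.0
    kde_grid_points: int = 512


@dataclass
class SynthConfig:
    height: int = 512
    width: int = 512
    n_seeds: int = 60
    boundary_width: int = 5
    noise_level: str = "low"
    weak_boundary_frac: float = 0.0
    jitter: float = 0.35


@dataclass
class PipelineConfig:
    image: ImageConfig = field(default_factory=ImageConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ced: CEDConfig = field(default_factory=CEDConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def ced_params(self) -> DiffusionParams:
        c = self.ced
        return DiffusionParams(tau=c.tau, sigma=c.sigma, rho=c.rho,
                               c1=c.c1, c2=c.c2, n_steps=c.n_steps)

    def postprocess_params(self) -> PostprocessParams:
        p = self.postprocess
        return PostprocessParams(t_area=p.t_area,
                                 closing_radius=p.closing_radius,
                                 erosion_radius=p.erosion_radius)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["preprocess"]["clahe_tiles"] = list(d["preprocess"]["clahe_tiles"])
        return d


_SECTIONS = {
    "image": ImageConfig,
    "preprocess": PreprocessConfig,
    "ced": CEDConfig,
    "postprocess": PostprocessConfig,
    "metrics": MetricsConfig,
    "synth": SynthConfig,
}


def _build_section(cls, data: dict, name: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        if key == "clahe_tiles":
            val = tuple(int(v) for v in val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in [{name}]: {exc}") from exc


def config_from_dict(data: dict) -> PipelineConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    sections = {
        name: _build_section(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    cfg = PipelineConfig(**sections)
    _validate(cfg)
    return cfg


def _validate(cfg: PipelineConfig) -> None:
    # Instantiating the parameter dataclasses runs their invariants.
    try:
        cfg.ced_params()
        cfg.postprocess_params()
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    if cfg.image.px_scale_um <= 0:
        raise ConfigError("image.px_scale_um must be > 0")
    if not (0.0 < cfg.metrics.encompass_frac <= 1.0):
        raise ConfigError("metrics.encompass_frac must lie in (0, 1]")
    if cfg.preprocess.nmf_max_iter < 1:
        raise ConfigError("preprocess.nmf_max_iter must be >= 1")
    if any(t < 1 for t in cfg.preprocess.clahe_tiles):
        raise ConfigError("preprocess.clahe_tiles entries must be >= 1")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the fully resolved config as YAML (round-trips losslessly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
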