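"""Pipeline configuration: one flat record of every tunable, loadable from
YAML/JSON and overridable by CLI flags (flags win)."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    threshold: float = 130.0  # soft-tissue gray threshold (8-bit scale)
    presmooth_sigma: float = 1.0  # pre-smoothing Gaussian sigma (px)
    r0_mm: float = 1.5  # smallest nodule radius
    r1_mm: float = 15.0  # largest nodule radius
    n_scales: int = 5
    scale_norm: bool = True  # sigma^2 response normalization
    rel_threshold: float = 0.1  # suspect binarization, relative to max response
    min_area_px: int = 4
    core_frac: float = 0.5  # scale-selective centroid core, relative to region peak
    prune_iterations: int = 8
    removal_factor: float = 1.5  # suspect removal dilation, in best-sigma units
    max_gap_factor: float = 2.0  # bridge reach, in removed-region diameters
    d_threshold_mm: float = 1.5  # d1/d2 decision threshold
    spacing_mm: float = 0.6
    window: int = 15  # skeleton pixels used by the local line fit
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "PipelineConfig":
        return self._validated(dataclasses.replace(self, **self._check_keys(kwargs)))

    @classmethod
    def _check_keys(cls, mapping: dict) -> dict:
        known = {f.name for f in dataclasses.fields(cls)}
        for key in mapping:
            if key not in known:
                raise ConfigurationError(f"unknown configuration key: {key!r}")
        return mapping

    @staticmethod
    def _validated(cfg: "PipelineConfig") -> "PipelineConfig":
        if cfg.spacing_mm <= 0:
            raise ConfigurationError(f"spacing_mm must be > 0, got {cfg.spacing_mm}")
        if not (0 < cfg.rel_threshold < 1):
            raise ConfigurationError(f"rel_threshold must be in (0, 1), got {cfg.rel_threshold}")
        if cfg.r0_mm <= 0 or cfg.r1_mm < cfg.r0_mm:
            raise ConfigurationError(f"need 0 < r0_mm <= r1_mm, got {cfg.r0_mm}, {cfg.r1_mm}")
        if cfg.d_threshold_mm <= 0:
            raise ConfigurationError("d_threshold_mm must be > 0")
        if cfg.prune_iterations < 0:
            raise ConfigurationError("prune_iterations must be >= 0")
        return cfg

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        return cls._validated(cls(**cls._check_keys(dict(mapping))))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            payload = json.loads(text)
        else:
            payload = yaml.safe_load(text)
        if payload is None:
            payload = {}
        if not isinstance(payload, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(payload)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
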