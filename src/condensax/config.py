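"""Run configuration: one structured YAML file drives the whole pipeline.

Every stochastic stage receives an explicit seed derived from the global
seed plus a fixed per-stage offset, so a run is reproducible from its
config alone.  Unknown keys are rejected.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields

import yaml

from .exceptions import ConfigError
from .rmc import FitConfig

#: fixed per-stage seed offsets (global seed + offset feeds each stage)
STAGE_SEED_OFFSETS = {
    "simulate": 100,
    "fit_blobs": 200,
    "fit_cylinders": 300,
    "metrics": 400,
    "xl_tables": 500,
}

_SIMULATE_KEYS = {"kind", "n_particles", "step_length", "sigma_blob",
                  "container_diameter", "window_sigma", "noise_fraction",
                  "q_min", "q_max", "n_q", "n_orientations", "geometry"}
_METRICS_KEYS = {"box_size", "min_count", "r_max", "dr", "fractal_q_min",
                 "fractal_q_max"}
_FIT_KEYS = {f.name for f in fields(FitConfig)}
_TOP_KEYS = {"seed", "stages", "simulate", "fit_blobs", "fit_cylinders", "metrics"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["simulate", "fit_blobs", "metrics"])
    simulate: dict = field(default_factory=dict)
    fit_blobs: dict = field(default_factory=dict)
    fit_cylinders: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {"simulate": _SIMULATE_KEYS, "fit_blobs": _FIT_KEYS,
                 "fit_cylinders": _FIT_KEYS, "metrics": _METRICS_KEYS}
        for section, keys in known.items():
            unknown = set(getattr(self, section)) - keys
            if unknown:
                raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
        for stage in self.stages:
            if stage not in STAGE_SEED_OFFSETS and stage != "fit_cylinders":
                raise ConfigError(f"unknown stage {stage!r}")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_mapping(data)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_SEED_OFFSETS[stage]) % (2**31)

    def content_hash(self) -> str:
        canonical = yaml.safe_dump({
            "seed": self.seed, "stages": self.stages, "simulate": self.simulate,
            "fit_blobs": self.fit_blobs, "fit_cylinders": self.fit_cylinders,
            "metrics": self.metrics}, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def fit_config(self, section: str, **overrides) -> FitConfig:
        params = dict(getattr(self, section))
        params.setdefault("seed", self.stage_seed(section))
        params.update(overrides)
        return FitConfig(**params)
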