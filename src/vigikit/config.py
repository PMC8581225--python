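"""Run configuration: YAML-serializable overrides for every pipeline stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import PreprocessConfig
from .staging import StagingConfig
from .synth import EEGSynthesisParams, TrajectoryParams


@dataclass
class RunConfig:
    """Seeded, serializable configuration of a pipeline run.

    The override dicts patch the corresponding config dataclasses; the seed
    is recorded in every output manifest.  ``to_dict``/``from_dict`` round
    trip losslessly through YAML.
    """

    seed: int = 0
    out: str = "vigikit_out"
    n_adhd: int = 4
    n_dep: int = 4
    n_segments: int = 480
    preprocess: dict = field(default_factory=dict)
    staging: dict = field(default_factory=dict)
    eeg: dict = field(default_factory=dict)
    adhd_trajectory: dict = field(default_factory=dict)
    dep_trajectory: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    # -- materialized stage configs ------------------------------------
    def preprocess_config(self) -> PreprocessConfig:
        return _patched(PreprocessConfig(), self.preprocess)

    def staging_config(self) -> StagingConfig:
        return _patched(StagingConfig(), self.staging)

    def eeg_params(self) -> EEGSynthesisParams:
        return _patched(EEGSynthesisParams(), self.eeg)


def _patched(obj, overrides: dict):
    for key, val in overrides.items():
        if not hasattr(obj, key):
            raise ValueError(f"{type(obj).__name__} has no field {key!r}")
        current = getattr(obj, key)
        if isinstance(current, tuple) and isinstance(val, list):
            val = tuple(val)
        setattr(obj, key, val)
    return obj


def patched_trajectory(base: TrajectoryParams, overrides: dict
                       ) -> TrajectoryParams:
    return _patched(dataclasses.replace(base), overrides)
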