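"""Run configuration: one YAML-backed record, hashed for provenance.

Every CLI output embeds ``config_hash`` so results can be traced to the
exact parameter set; re-running the same hash and seed reproduces outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .generator import GeneratorConfig
from .reward import RewardConfig
from .rl import RLConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Merged reward + RL + generator configuration plus file paths."""

    reward: RewardConfig = field(default_factory=RewardConfig)
    rl: RLConfig = field(default_factory=RLConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    corpus_path: str | None = None
    reference_sdf: str | None = None
    decorations_path: str | None = None
    output_dir: str = "."
    backend: str = "open"
    seed: int = 42

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(payload: dict) -> str:
    """Short stable digest of a config mapping."""
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config; missing sections fall back to defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(
        reward=_build(RewardConfig, raw.get("reward", {})),
        rl=_build(RLConfig, raw.get("rl", {})),
        generator=_build(GeneratorConfig, raw.get("generator", {})),
        corpus_path=raw.get("corpus_path"),
        reference_sdf=raw.get("reference_sdf"),
        decorations_path=raw.get("decorations_path"),
        output_dir=raw.get("output_dir", "."),
        backend=raw.get("backend", "open"),
        seed=raw.get("seed", 42),
    )
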