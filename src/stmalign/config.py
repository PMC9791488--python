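"""YAML-backed configuration for training runs.

A config file carries two top-level sections, ``train`` and ``env``,
whose keys map directly onto the fields of
:class:`~stmalign.control.TrainConfig` and
:class:`~stmalign.environment.EnvConfig`.  Missing keys fall back to the
defaults; unknown keys are rejected to catch typos early.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .control import TrainConfig
from .environment import EnvConfig


def _build(cls, section: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
    }
    return cls(**coerced)


def load_config(path) -> tuple[TrainConfig, EnvConfig]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return (
        _build(TrainConfig, raw.get("train", {})),
        _build(EnvConfig, raw.get("env", {})),
    )


def save_config(path, train_cfg: TrainConfig, env_cfg: EnvConfig) -> None:
    def plain(cfg):
        return {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in dataclasses.asdict(cfg).items()
        }

    Path(path).write_text(
        yaml.safe_dump({"train": plain(train_cfg), "env": plain(env_cfg)})
    )
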