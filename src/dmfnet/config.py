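"""YAML configuration loading for model, loss and training settings."""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .augment import AugmentPolicy
from .cv import TrainConfig
from .losses import LossWeights
from .model import ModelConfig

_SECTIONS = {"model": ModelConfig, "loss": LossWeights, "train": TrainConfig,
             "augment": AugmentPolicy}


def load_config(path: str) -> dict:
    """Read a YAML file with optional ``model:``/``loss:``/``train:``/
    ``augment:`` sections into the corresponding dataclasses (missing
    sections and fields fall back to their defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for key, cls in _SECTIONS.items():
        section = raw.get(key, {}) or {}
        unknown = set(section) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown {key} config key(s): {sorted(unknown)}")
        if "erase_area" in section:
            section["erase_area"] = tuple(section["erase_area"])
        out[key] = cls(**section)
    return out


def save_config(configs: dict, path: str):
    raw = {k: asdict(v) for k, v in configs.items() if k in _SECTIONS}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
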