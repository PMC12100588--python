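"""Structured configuration: YAML with nested sections, plus provenance hashing.

Every pipeline stage logs the hash of the configuration it ran under so
outputs can be traced back to their parameterisation.
"""
from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import yaml

from .synthetic import CampaignConfig


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration root must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def campaign_config(cfg: dict) -> CampaignConfig:
    """Build a CampaignConfig from the ``campaign`` section, merging defaults."""
    section = cfg.get("campaign", {})
    base = CampaignConfig()
    fields = {f.name for f in dataclasses.fields(CampaignConfig)}
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"unknown campaign config key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for key, value in section.items():
        default = getattr(base, key)
        if isinstance(default, dict) and isinstance(value, dict):
            merged = dict(default)
            merged.update(value)
            kwargs[key] = merged
        else:
            kwargs[key] = value
    return dataclasses.replace(base, **kwargs)
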