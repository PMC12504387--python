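"""Structured run configuration: YAML files, overrides, resolved output.

A run config is a YAML file with up to three sections — ``synthetic``,
``augment`` and ``train`` — whose keys mirror :class:`SyntheticSpec`,
:class:`AugmentConfig` and :class:`TrainConfig`.  Unknown sections or keys
are rejected with the offending name.  CLI flags override file values
(flag > file > dataclass default), and every run writes its fully resolved
configuration back to disk as JSON so it can be re-run verbatim.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, Optional, Type

import yaml

from .compose import AugmentConfig
from .errors import ConfigError
from .synthetic import SyntheticSpec
from .train import TrainConfig

SECTION_TYPES: Dict[str, type] = {
    "synthetic": SyntheticSpec,
    "augment": AugmentConfig,
    "train": TrainConfig,
}


def _known_fields(cls: type) -> set:
    return {f.name for f in dataclasses.fields(cls)}


def load_config(path: Optional[Path]) -> Dict[str, Dict[str, Any]]:
    """Parse a YAML config file into raw per-section dictionaries."""
    if path is None:
        return {}
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    for section, content in raw.items():
        if section not in SECTION_TYPES:
            raise ConfigError(f"unknown config section {section!r}")
        if content is None:
            raw[section] = {}
        elif not isinstance(content, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        else:
            unknown = set(content) - _known_fields(SECTION_TYPES[section])
            if unknown:
                raise ConfigError(
                    f"unknown key(s) {sorted(unknown)} in section {section!r}"
                )
    return raw


def build_section(section: str, file_values: Dict[str, Dict[str, Any]],
                  **overrides: Any):
    """Instantiate one section's dataclass: flag > file > default."""
    cls = SECTION_TYPES[section]
    values = dict(file_values.get(section, {}))
    for key, value in overrides.items():
        if value is not None:
            if key not in _known_fields(cls):
                raise ConfigError(f"unknown key {key!r} for section {section!r}")
            values[key] = value
    try:
        return cls(**values)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid {section} config: {exc}") from exc


def write_resolved(sections: Dict[str, Any], path: Path) -> None:
    """Dump the resolved dataclass sections as sorted JSON."""
    payload = {
        name: dataclasses.asdict(obj) for name, obj in sections.items()
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
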