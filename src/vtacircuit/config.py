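"""Configuration loading and validation.

A run is fully described by a YAML file with flat sections mirroring the
parameter types: ``circuit``, ``receptors``, ``protocol``, ``learning``,
``pharmacology``, ``opto``, ``decision``, plus a top-level ``seed`` and
``schema_version``. Every key is optional — an empty file yields the full
default configuration — and unknown keys are rejected with their path so
typos do not silently fall back to defaults.

Default provenance: printed model constants carry their published values
(time constants, baselines, sigmoid shapes, r, w_alpha4b2, w_ach, f_max, h,
alpha_T, the opto and nicotine protocols, the decision task constants); the
receptor gate constants and the weights w_G-D, w_PPT-D, w_PPT-G, w_CS, c
and alpha_V are calibrated as documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .circuit import CircuitParams, TrialProtocol
from .experiments import DecisionTaskSpec, OptoProtocol
from .plasticity import LearningRates
from .receptors import PharmacologySchedule, ReceptorParams

__all__ = ["RunConfig", "load_config", "save_config", "config_to_dict"]


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters for one run."""

    circuit: CircuitParams = field(default_factory=CircuitParams)
    receptors: ReceptorParams = field(default_factory=ReceptorParams)
    protocol: TrialProtocol = field(default_factory=TrialProtocol)
    learning: LearningRates = field(default_factory=LearningRates)
    pharmacology: PharmacologySchedule = field(
        default_factory=PharmacologySchedule.control
    )
    opto: OptoProtocol = field(default_factory=OptoProtocol)
    decision: DecisionTaskSpec = field(default_factory=DecisionTaskSpec)
    seed: int = 0
    schema_version: int = 1


class ConfigError(ValueError):
    """Raised on schema violations, carrying the offending key path."""


def _build(defaults, data: dict, path: str):
    """Update the dataclass instance ``defaults`` from a mapping, recursing
    into nested dataclass fields and rejecting unknown keys with their path."""
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(defaults)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        current = getattr(defaults, name)
        if is_dataclass(current) and isinstance(value, dict):
            kwargs[name] = _build(current, value, f"{path}.{name}")
        elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return dataclasses.replace(defaults, **kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


_SECTIONS = {
    "circuit": CircuitParams,
    "receptors": ReceptorParams,
    "protocol": TrialProtocol,
    "learning": LearningRates,
    "pharmacology": PharmacologySchedule,
    "opto": OptoProtocol,
    "decision": DecisionTaskSpec,
}


def config_from_dict(data: dict | None) -> RunConfig:
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("top level: expected a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed", "schema_version"}
    if unknown:
        raise ConfigError(f"top level: unknown key(s) {sorted(unknown)}")
    base = RunConfig()
    kwargs = {}
    for name in _SECTIONS:
        if name in data:
            kwargs[name] = _build(getattr(base, name), data[name], name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "schema_version" in data:
        if data["schema_version"] != 1:
            raise ConfigError("schema_version: only version 1 is supported")
        kwargs["schema_version"] = 1
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; an empty file gives full defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return config_from_dict(data)


def _to_plain(obj):
    if is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(x) for x in obj]
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    return _to_plain(cfg)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
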