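"""Study configuration: defaults, YAML loading and validation.

A :class:`StudyConfig` bundles the per-stage configs.  Validation fills
defaults, rejects unknown keys, and reports every violation with its
field path (e.g. ``inference.tfce_dh``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .decoding import DecoderConfig
from .inference import InferenceConfig
from .preprocess import PreprocessConfig
from .searchlight import SearchlightConfig
from .simulate import SignalComponent, SimulationConfig


@dataclass
class StudyConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    searchlight: SearchlightConfig = field(default_factory=SearchlightConfig)
    output_dir: str = "megscenes-output"
    master_seed: int = 0


class ConfigError(ValueError):
    """Itemized configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "preprocess": PreprocessConfig,
    "decoder": DecoderConfig,
    "inference": InferenceConfig,
    "searchlight": SearchlightConfig,
}


def _coerce(value, fld: dataclasses.Field, path: str, problems: list[str]):
    if fld.name == "components":
        out = []
        for i, comp in enumerate(value):
            if isinstance(comp, SignalComponent):
                out.append(comp)
                continue
            known = {f.name for f in dataclasses.fields(SignalComponent)}
            unknown = set(comp) - known
            if unknown:
                problems.append(f"{path}[{i}]: unknown keys {sorted(unknown)}")
                continue
            try:
                out.append(SignalComponent(**comp))
            except (TypeError, ValueError) as exc:
                problems.append(f"{path}[{i}]: {exc}")
        return out
    if isinstance(value, list):
        return tuple(value)
    return value


def _build_section(cls, raw: dict, section: str, problems: list[str]):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(known)
    for key in sorted(unknown):
        problems.append(f"{section}.{key}: unknown key")
    kwargs = {
        k: _coerce(v, known[k], f"{section}.{k}", problems)
        for k, v in raw.items()
        if k in known
    }
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        problems.append(f"{section}: {exc}")
        return cls()


def validate_config(raw: dict | None) -> StudyConfig:
    """Build a validated StudyConfig from a parsed document.

    An empty document yields the full-default study.  Unknown keys and
    invariant violations are collected and raised together.
    """
    raw = dict(raw or {})
    problems: list[str] = []
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        sub = raw.pop(section, None)
        if sub is None:
            kwargs[section] = cls()
        elif not isinstance(sub, dict):
            problems.append(f"{section}: expected a mapping")
        else:
            kwargs[section] = _build_section(cls, sub, section, problems)
    for scalar in ("output_dir", "master_seed"):
        if scalar in raw:
            kwargs[scalar] = raw.pop(scalar)
    for key in sorted(raw):
        problems.append(f"{key}: unknown key")
    if problems:
        raise ConfigError(problems)
    config = StudyConfig(**kwargs)
    # cross-section checks
    if config.searchlight.neighborhood_size > config.simulation.n_channels:
        raise ConfigError(
            [
                "searchlight.neighborhood_size: "
                f"{config.searchlight.neighborhood_size} exceeds the "
                f"{config.simulation.n_channels}-channel layout"
            ]
        )
    return config


def load_config(path: str | Path | None) -> StudyConfig:
    if path is None:
        return validate_config({})
    with open(path) as f:
        return validate_config(yaml.safe_load(f))


def config_hash(config: StudyConfig) -> str:
    """Stable content hash of a study configuration."""

    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [encode(o) for o in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in sorted(obj.items())}
        return obj

    blob = json.dumps(encode(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
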