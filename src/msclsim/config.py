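"""Run configuration: validated, defaulted, round-trippable.

A run is fully described by a small YAML file; unknown keys are rejected by
name so typos cannot silently fall back to defaults.  The resolved
configuration is echoed verbatim into every run log, which makes any run
reproducible from its output directory alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

from .geometry import IdealizedParams
from .solver import MechanicsParams, SolverConfig
from .vdw import VdwLaw

__all__ = ["RunConfig", "ConfigError", "parse_config", "serialize_config"]


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending keys."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    # exactly one model source: a structure file or the idealized build
    structure_file: str | None = None
    idealized: IdealizedParams = field(default_factory=IdealizedParams)
    variant: str = "WT"
    solver: SolverConfig = field(default_factory=SolverConfig)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    output_dir: str = "runs"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.variant not in ("WT", "DELTA_NTERM", "+2G", "+5G"):
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.structure_file is not None and not Path(self.structure_file).exists():
            raise ConfigError(f"structure file not found: {self.structure_file}")


_SECTION_TYPES = {
    "idealized": IdealizedParams,
    "solver": SolverConfig,
    "mechanics": MechanicsParams,
}


def _build_section(cls, data: dict[str, Any], path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys under {path!r}: {sorted(unknown)}")
    kwargs = dict(data)
    if cls is MechanicsParams and "vdw" in kwargs:
        vdw = kwargs["vdw"]
        if isinstance(vdw, dict):
            vallowed = {f.name for f in fields(VdwLaw)}
            vunknown = set(vdw) - vallowed
            if vunknown:
                raise ConfigError(f"unknown keys under {path}.vdw: {sorted(vunknown)}")
            if "exponents" in vdw:
                vdw = {**vdw, "exponents": tuple(vdw["exponents"])}
            kwargs["vdw"] = VdwLaw(**vdw)
    for name in ("tm1_range", "tm2_range", "nterm_range"):
        if name in kwargs and isinstance(kwargs[name], list):
            kwargs[name] = tuple(kwargs[name])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value under {path!r}: {exc}") from exc


def parse_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys raise a :class:`ConfigError` listing them; type and value
    violations name the config path at fault.  Missing sections take their
    documented defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top_allowed = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ConfigError(f"unknown keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def serialize_config(config: RunConfig) -> str:
    """YAML text that :func:`parse_config` reads back to an equal config."""
    data = asdict(config)
    vdw = data["mechanics"]["vdw"]
    vdw["exponents"] = list(vdw["exponents"])
    for name in ("tm1_range", "tm2_range", "nterm_range"):
        data["idealized"][name] = list(data["idealized"][name])
    return yaml.safe_dump(data, sort_keys=False)
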