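"""Run configuration: defaults ← config file ← command-line overrides.

Mesh units must always be explicit (``cm``, ``m`` or ``mm``) — silent
metre/millimetre confusion would corrupt inertia values by five orders of
magnitude, so no autodetection is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .mesh import UNIT_TO_CM


class ConfigError(ValueError):
    """Raised for malformed files, unknown keys or invalid values."""


@dataclass
class RunConfig:
    units: str = "cm"
    densities: str = "literature"  # "literature", "uniform1000" or a CSV path
    scheme: str | None = None
    frame: str | None = None
    outdir: str = "."
    seed: int = 0
    verbosity: int = 0

    def validate(self) -> "RunConfig":
        if self.units not in UNIT_TO_CM:
            raise ConfigError(
                f"invalid units {self.units!r}; expected one of {sorted(UNIT_TO_CM)}"
            )
        return self


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` with precedence defaults < file < overrides.

    Unknown keys are rejected; YAML/JSON syntax errors are reported with the
    offending line number.
    """
    valid = {f.name for f in fields(RunConfig)}
    data: dict = {}
    if path is not None:
        try:
            with open(path) as fh:
                loaded = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark is not None else ""
            raise ConfigError(f"malformed config file {path}{line}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides or {})
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data).validate()
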