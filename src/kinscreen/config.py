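"""Pipeline configuration: YAML-backed, schema-checked, hashable.

Defaults mirror the screening protocol the package targets: a 25-95 degC
ramp, triplicate wells, a 2x-DMSO-SD hit threshold with negative shifts
clamped to 0, and a compound concentration of 12.5 uM recorded as metadata
(it plays no numeric role in the analysis).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import MalformedInputError
from .melt import FitOptions
from .simulate import CurveParams, ScreenScenario


@dataclass(frozen=True)
class SelectionParams:
    threshold: float = 2.0
    aggregation: str = "max"
    alpha: float = 0.5
    rounds: int = 2
    k: int = 141

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise MalformedInputError("alpha must lie in [0, 1]")
        if self.rounds < 0 or self.k <= 0:
            raise MalformedInputError("rounds must be >= 0 and k positive")
        if self.aggregation not in {"max", "mean"}:
            raise MalformedInputError("aggregation must be 'max' or 'mean'")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    multiplier: float = 2.0
    clamp: bool = True
    compound_concentration_um: float = 12.5  # metadata only
    log_level: str = "INFO"
    fit: FitOptions = field(default_factory=FitOptions)
    curve: CurveParams = field(default_factory=CurveParams)
    scenario: ScreenScenario = field(default_factory=ScreenScenario)
    selection: SelectionParams = field(default_factory=SelectionParams)

    def __post_init__(self):
        if self.multiplier <= 0:
            raise MalformedInputError("multiplier must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable digest of the full configuration (for output stamping)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stamp(self) -> str:
        return f"config_sha256={self.config_hash()} seed={self.seed}"


_SECTIONS = {
    "fit": FitOptions,
    "curve": CurveParams,
    "scenario": ScreenScenario,
    "selection": SelectionParams,
}


def _build(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise MalformedInputError(f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            coerced[f.name] = tuple(value) if isinstance(value, list) else value
    return cls(**coerced)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, None)
        if section is not None:
            if not isinstance(section, dict):
                raise MalformedInputError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build(cls, section)
    top = _build(PipelineConfig, data)
    return dataclasses.replace(top, **kwargs)


def load_config(path: Path | None = None) -> PipelineConfig:
    """Load a YAML config; a missing path gives the documented defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise MalformedInputError(f"{path}: config must be a YAML mapping")
    return config_from_dict(raw)
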