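"""Declarative analysis configuration.

A single YAML document pins every numeric choice of a population analysis —
which distance table, which pairs serve as reference and marker, how
conformers are split into open/closed families, the measured rates, and the
Monte-Carlo settings — so a report is reproducible from its embedded
configuration alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .distances import MARKER_THRESHOLD
from .errors import ConfigError

__all__ = ["RateSpec", "ClassificationSpec", "UncertaintySpec", "AnalysisConfig"]


@dataclass(frozen=True)
class RateSpec:
    """One measured cross-relaxation rate (s^-1) with its uncertainty."""

    value: float
    stderr: float = 0.0

    def __post_init__(self):
        if self.value <= 0 or self.stderr < 0:
            raise ConfigError("rate must be positive and stderr nonnegative")


@dataclass(frozen=True)
class ClassificationSpec:
    criterion: str = "explicit"
    open: tuple[str, ...] = ()
    closed: tuple[str, ...] = ()
    threshold: float = MARKER_THRESHOLD

    def __post_init__(self):
        if self.criterion not in ("explicit", "marker_distance", "fluorine_distance"):
            raise ConfigError(f"unknown classification criterion {self.criterion!r}")
        object.__setattr__(self, "open", tuple(self.open))
        object.__setattr__(self, "closed", tuple(self.closed))


@dataclass(frozen=True)
class UncertaintySpec:
    n_draws: int = 100_000
    seed: int = 0


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a population analysis needs, in one declarative object."""

    solvent: str
    distance_table: str  # path, or builtin:qc / builtin:solid
    reference_pair: str
    marker_pair: str
    sigma_reference: RateSpec
    sigma_marker: RateSpec
    classification: ClassificationSpec = ClassificationSpec()
    uncertainty: UncertaintySpec = UncertaintySpec()
    output_dir: str | None = None

    def __post_init__(self):
        if self.reference_pair == self.marker_pair:
            raise ConfigError("reference and marker pair must differ")

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        try:
            raw["sigma_reference"] = RateSpec(**raw["sigma_reference"])
            raw["sigma_marker"] = RateSpec(**raw["sigma_marker"])
        except KeyError as exc:
            raise ConfigError(f"missing required config key: {exc}") from None
        if "classification" in raw:
            raw["classification"] = ClassificationSpec(**raw["classification"])
        if "uncertainty" in raw:
            raw["uncertainty"] = UncertaintySpec(**raw["uncertainty"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {
            f.name
            for f in dataclasses.fields(cls)
            if f.default is dataclasses.MISSING
            and f.default_factory is dataclasses.MISSING
        } - set(raw)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, source: str | Path) -> "AnalysisConfig":
        text = (
            source
            if isinstance(source, str) and "\n" in source
            else Path(source).read_text()
        )
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def builtin(cls, name: str) -> "AnalysisConfig":
        """Load a packaged analysis configuration by name
        (cdcl3_qc, dmso_qc, cdcl3_solid, dmso_solid)."""
        path = resources.files("noesypop.data.configs").joinpath(f"{name}.yaml")
        try:
            text = path.read_text()
        except FileNotFoundError:
            raise ConfigError(f"no packaged config named {name!r}") from None
        return cls.from_yaml(text)
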