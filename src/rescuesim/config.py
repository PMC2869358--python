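"""Configuration loading, validation and provenance.

A run is fully specified by a :class:`Config` (plus a seed).  Configs are
flat YAML or JSON documents with dotted sections mirroring the model's
module structure; every numeric field is validated against its domain at
load time and unknown keys are rejected.  The effective post-default
config can be dumped back out and hashes stably, so every result file can
carry the (seed, config-hash) pair that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cells import PopulationRanges
from .signaling import ResistanceParams, SignalConfig, SignalSpec, Thresholds


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GridSection(_Section):
    extents: tuple[int, int, int] = (20, 20, 20)

    @model_validator(mode="after")
    def _check(self):
        if any(e < 3 for e in self.extents):
            raise ValueError("grid extents must each be >= 3")
        return self


class PopulationSection(_Section):
    ratio: Optional[int] = 6
    normal_prolif: Optional[tuple[float, float]] = None
    tumor_prolif: Optional[tuple[float, float]] = None
    normal_death: Optional[tuple[float, float]] = None
    tumor_death: Optional[tuple[float, float]] = None
    skew: float = Field(0.1, ge=0.0, le=1.0)
    generation_potential: int = Field(50, ge=1)
    suppression_factor: float = Field(0.5, ge=0.0, le=1.0)
    mutation_prob: float = Field(0.0, ge=0.0, le=1.0)
    allow_displacement: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.ratio is None and self.normal_prolif is None:
            raise ValueError("population requires a ratio preset (6, 10, 20) or explicit ranges")
        self.ranges()  # validates preset label and range domains
        return self

    def ranges(self) -> PopulationRanges:
        if self.ratio is not None and self.normal_prolif is None:
            base = PopulationRanges.from_ratio(self.ratio)
        else:
            base = PopulationRanges(
                normal_prolif=self.normal_prolif, ratio_label=self.ratio
            )
        kw = {}
        for name in ("tumor_prolif", "normal_death", "tumor_death"):
            if getattr(self, name) is not None:
                kw[name] = getattr(self, name)
        if kw:
            base = PopulationRanges(
                normal_prolif=base.normal_prolif,
                tumor_prolif=kw.get("tumor_prolif", base.tumor_prolif),
                normal_death=kw.get("normal_death", base.normal_death),
                tumor_death=kw.get("tumor_death", base.tumor_death),
                ratio_label=base.ratio_label,
            )
        return base


class SignalsSection(_Section):
    table1_set: Optional[int] = 2
    tumor_im_dying: Optional[tuple[int, float]] = None
    normal_im_dying: Optional[tuple[int, float]] = None
    normal_please_die: Optional[tuple[int, float]] = None
    decay: str = "linear"
    metric: str = "chebyshev"
    retention: float = Field(0.9, ge=0.0, le=1.0)
    violation_radius: int = Field(1, ge=1, le=2)
    enable_please_die: bool = True
    enable_im_dying: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.decay not in ("linear", "exponential"):
            raise ValueError(f"decay must be 'linear' or 'exponential', got {self.decay!r}")
        if self.metric not in ("chebyshev", "euclidean"):
            raise ValueError(f"metric must be 'chebyshev' or 'euclidean', got {self.metric!r}")
        self.signal_config()
        return self

    def signal_config(self) -> SignalConfig:
        if self.table1_set is not None:
            base = SignalConfig.from_table1(self.table1_set, decay=self.decay, metric=self.metric)
        else:
            if None in (self.tumor_im_dying, self.normal_im_dying, self.normal_please_die):
                raise ValueError("signals require a table1_set label or all three explicit specs")
            base = None
        specs = {}
        for name in ("tumor_im_dying", "normal_im_dying", "normal_please_die"):
            explicit = getattr(self, name)
            specs[name] = SignalSpec(*explicit) if explicit is not None else base.spec(name)
        return SignalConfig(decay=self.decay, metric=self.metric, **specs)


class ThresholdsSection(_Section):
    high_tumor: float = 1.0
    high_normal: float = 16.0
    low_please_die: float = 2.0
    low_repop: float = 1.0
    count_tumor: int = 1
    count_normal: int = 1
    acceleration_factor: float = Field(2.0, ge=1.0)
    acceleration_steps: int = Field(5, ge=1)

    @model_validator(mode="after")
    def _check(self):
        self.thresholds()
        return self

    def thresholds(self) -> Thresholds:
        return Thresholds(
            high_tumor=self.high_tumor,
            high_normal=self.high_normal,
            low_normal_please_die=self.low_please_die,
            low_normal_repop=self.low_repop,
            count_tumor=self.count_tumor,
            count_normal=self.count_normal,
            acceleration_factor=self.acceleration_factor,
            acceleration_steps=self.acceleration_steps,
        )


class ResistanceSection(_Section):
    ignore_prob: float = Field(0.0, ge=0.0, le=1.0)
    fail_emit_prob: float = Field(0.0, ge=0.0, le=1.0)

    def resistance(self) -> ResistanceParams:
        return ResistanceParams(self.ignore_prob, self.fail_emit_prob)


class EngineSection(_Section):
    max_steps: int = Field(500, ge=1)
    growth_step_cap: int = Field(5000, ge=1)
    confluence_frac: float = Field(0.99, gt=0.0, le=1.0)
    integrity_frac: float = Field(0.5, ge=0.0, le=1.0)
    plant: bool = True
    plant_site: Optional[tuple[int, int, int]] = None
    activation_delay: int = Field(10, ge=0)
    activation_volume: Optional[float] = Field(None, gt=0.0, lt=1.0)
    senescence_age: int = Field(200, ge=1)
    crushed_emit: bool = True


class Config(_Section):
    """Complete, validated simulation configuration."""

    grid: GridSection = Field(default_factory=GridSection)
    population: PopulationSection = Field(default_factory=PopulationSection)
    signals: SignalsSection = Field(default_factory=SignalsSection)
    thresholds: ThresholdsSection = Field(default_factory=ThresholdsSection)
    resistance: ResistanceSection = Field(default_factory=ResistanceSection)
    engine: EngineSection = Field(default_factory=EngineSection)
    seed: Optional[int] = None

    # -- resolved domain objects --------------------------------------
    def ranges(self) -> PopulationRanges:
        return self.population.ranges()

    def signal_config(self) -> SignalConfig:
        return self.signals.signal_config()

    def thresholds_obj(self) -> Thresholds:
        return self.thresholds.thresholds()

    def resistance_obj(self) -> ResistanceParams:
        return self.resistance.resistance()

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def dump_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def hash(self) -> str:
        """Stable short hash of the effective (post-default) config."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def with_overrides(self, **dotted) -> "Config":
        """Copy with dotted-key overrides, e.g. ``resistance.ignore_prob=0.68``."""
        data = self.to_dict()
        for key, value in dotted.items():
            parts = key.split("__") if "__" in key else key.split(".")
            node = data
            for p in parts[:-1]:
                node = node[p]
            node[parts[-1]] = value
        return Config(**data)


def make_config(**dotted) -> Config:
    """Default config with dotted overrides (``engine__activation_delay=0``)."""
    return Config().with_overrides(**dotted)


def load_config(path: str | Path) -> Config:
    """Load and validate a YAML or JSON config file, filling defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"could not parse config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping at top level")
    # convenience: accept flat shorthand keys at top level
    shorthand = {"ratio": ("population", "ratio"), "table1_set": ("signals", "table1_set")}
    for short, (section, key) in shorthand.items():
        if short in data:
            data.setdefault(section, {})[key] = data.pop(short)
    return Config(**data)
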