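"""Pipeline configuration: fully serializable, reproducible from seed alone."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .synthetic import CohortSpec, SignalParams
from .types import Cohort, ConfigurationError, Study


@dataclass
class CohortConfig:
    study: str
    cohort: str
    n: int
    severity_mean: float
    severity_sd: float

    def to_spec(self, seed: int) -> CohortSpec:
        return CohortSpec(
            study=Study(self.study),
            cohort=Cohort(self.cohort),
            n_participants=self.n,
            severity_mean=self.severity_mean,
            severity_sd=self.severity_sd,
            seed=seed,
        )


def default_cohorts() -> list[CohortConfig]:
    """Three-study layout: one manifest cohort per study plus the
    control/premanifest cohorts of the fully remote study."""
    return [
        CohortConfig("OLE", "manifest", 16, 0.55, 0.15),
        CohortConfig("HD_NHS", "manifest", 16, 0.50, 0.15),
        CohortConfig("DIGITAL_HD", "manifest", 16, 0.50, 0.15),
        CohortConfig("DIGITAL_HD", "premanifest", 14, 0.15, 0.06),
        CohortConfig("DIGITAL_HD", "control", 14, 0.02, 0.02),
    ]


@dataclass
class PipelineConfig:
    seed: int = 0
    n_days: int = 28
    adherence_prob: float = 0.80
    pocket_prob: float = 0.12
    cohorts: list[CohortConfig] = field(default_factory=default_cohorts)
    signal_params: dict[str, Any] = field(default_factory=dict)
    placement_rule: bool = True
    n_min_overrides: dict[str, int] = field(default_factory=dict)
    correlation_methods: dict[str, str] = field(default_factory=dict)
    report_precision: int = 2
    outdir: str = "activemon_run"

    def make_signal_params(self) -> SignalParams:
        known = {f.name for f in dataclasses.fields(SignalParams)}
        bad = set(self.signal_params) - known
        if bad:
            raise ConfigurationError(f"unknown signal parameters: {sorted(bad)}")
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in self.signal_params.items()
        }
        return SignalParams(**kwargs)

    def cohort_specs(self) -> list[CohortSpec]:
        return [c.to_spec(self.seed) for c in self.cohorts]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohorts = d.pop("cohorts", None)
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if cohorts is not None:
            cfg.cohorts = [CohortConfig(**c) for c in cohorts]
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                payload = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(payload, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
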