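"""Run configuration: nested, validated, loadable from YAML.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently running with defaults.  Every value is validated against the module
invariants at load time by constructing the corresponding spec objects.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .event_detection import DEFAULT_MIN_GCT_MS, DEFAULT_ROI_MS, ThresholdSpec
from .gait_features import DEFAULT_WINDOW_MS, ClassBoundaries
from .preprocess import FilterSpec

__all__ = ["ConfigError", "RunConfig", "FilterConfig", "DetectConfig", "FeaturesConfig", "CalibrationConfig"]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


def _from_mapping(cls, data: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section} config: {exc}") from exc


@dataclass(frozen=True)
class FilterConfig:
    order: int = 4
    low_cut_hz: float = 0.5
    high_cut_hz: float = 5.0
    zero_phase: bool = True

    def spec(self) -> FilterSpec:
        return FilterSpec(**asdict(self))


@dataclass(frozen=True)
class DetectConfig:
    maxima_fraction: float = 0.4
    maxima_window_s: float = 2.5
    refractory_fraction: float | None = 0.5
    roi_ms: float = DEFAULT_ROI_MS
    min_gct_ms: float = DEFAULT_MIN_GCT_MS
    ic_refine_samples: int = 2
    fc_refine_samples: int = 6

    def spec(self) -> ThresholdSpec:
        return ThresholdSpec(
            maxima_fraction=self.maxima_fraction,
            maxima_window_s=self.maxima_window_s,
            refractory_fraction=self.refractory_fraction,
        )


@dataclass(frozen=True)
class FeaturesConfig:
    window_ms: float = DEFAULT_WINDOW_MS
    pronation_slight_deg: float = 2.0
    pronation_pronated_deg: float = 5.0
    footstrike_heel_dps: float = -50.0
    footstrike_fore_dps: float = 50.0

    def boundaries(self) -> ClassBoundaries:
        return ClassBoundaries(
            pronation_slight_deg=self.pronation_slight_deg,
            pronation_pronated_deg=self.pronation_pronated_deg,
            footstrike_heel_dps=self.footstrike_heel_dps,
            footstrike_fore_dps=self.footstrike_fore_dps,
        )


@dataclass(frozen=True)
class CalibrationConfig:
    #: length (s) of the static-stance window at the start of the recording;
    #: None skips calibration.
    window_s: float | None = None


@dataclass(frozen=True)
class RunConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)

    def __post_init__(self) -> None:
        # validate eagerly against the module invariants
        try:
            self.filter.spec()
            self.detect.spec()
            self.features.boundaries()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if self.detect.roi_ms <= 0 or self.detect.min_gct_ms < 0:
            raise ConfigError("roi_ms must be positive and min_gct_ms non-negative")
        if self.detect.min_gct_ms >= self.detect.roi_ms:
            raise ConfigError("min_gct_ms must be below roi_ms")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {"filter": FilterConfig, "detect": DetectConfig,
                    "features": FeaturesConfig, "calibration": CalibrationConfig}
        unknown = set(data) - set(sections)
        if unknown:
            raise ConfigError(f"unknown top-level section(s) {sorted(unknown)}")
        kwargs = {
            name: _from_mapping(section_cls, data.get(name, {}) or {}, name)
            for name, section_cls in sections.items()
        }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root in {path} must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short provenance hash recorded in every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
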