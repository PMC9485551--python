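"""Pronation severity and foot-strike location around each initial contact.

Rotational velocity is observed in a short window centered on the IC (the
same 167 ms / 10 Hz window used for the noise analysis).  Frontal-plane roll
velocity is integrated from the IC over the trailing half-window to a roll
angle in degrees, making the classic "5 degrees or greater = pronated" rule
directly applicable; the sagittal-plane (pitch) mean velocity encodes whether
the heel (strongly negative), mid-foot (near zero) or forefoot (strongly
positive) strikes first.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .event_detection import StepTiming
from .imu_io import FOOTSTRIKE_CLASSES, PRONATION_CLASSES, ImuRecording

__all__ = [
    "ClassBoundaries",
    "StepFeature",
    "BoutResult",
    "extract_step_features",
    "classify_pronation",
    "classify_footstrike",
    "summarize_bout",
    "steps_to_frame",
    "write_step_csv",
    "write_bout_json",
]

DEFAULT_WINDOW_MS = 167.0

# tie-breaks resolve toward the more severe / more injury-relevant class
_PRONATION_SEVERITY = ("pronated", "slight", "neutral")
_FOOTSTRIKE_SEVERITY = ("heel", "mid", "fore")


@dataclass(frozen=True)
class ClassBoundaries:
    """Class boundaries for pronation (deg) and foot strike (deg/s).

    The 5-degree pronated bound is the published rule; the neutral/slight
    bound and the ±50 dps foot-strike velocity bounds are configuration
    defaults of this package.
    """

    pronation_slight_deg: float = 2.0
    pronation_pronated_deg: float = 5.0
    footstrike_heel_dps: float = -50.0
    footstrike_fore_dps: float = 50.0

    def __post_init__(self) -> None:
        if not 0 <= self.pronation_slight_deg < self.pronation_pronated_deg:
            raise ValueError("need 0 <= pronation_slight_deg < pronation_pronated_deg")
        if not self.footstrike_heel_dps < self.footstrike_fore_dps:
            raise ValueError("need footstrike_heel_dps < footstrike_fore_dps")


def classify_pronation(pronation_deg: float, boundaries: ClassBoundaries | None = None) -> str:
    """neutral / slight / pronated from the absolute roll angle.

    The pronated bound is inclusive ("5 degrees or greater").
    """
    b = boundaries or ClassBoundaries()
    a = abs(pronation_deg)
    if a < b.pronation_slight_deg:
        return "neutral"
    if a < b.pronation_pronated_deg:
        return "slight"
    return "pronated"


def classify_footstrike(pitch_mean_dps: float, boundaries: ClassBoundaries | None = None) -> str:
    """heel / mid / fore from the signed mean pitch velocity around the IC."""
    b = boundaries or ClassBoundaries()
    if pitch_mean_dps < b.footstrike_heel_dps:
        return "heel"
    if pitch_mean_dps > b.footstrike_fore_dps:
        return "fore"
    return "mid"


@dataclass(frozen=True)
class StepFeature:
    """Per-step features and class labels."""

    timing: StepTiming
    roll_mean_dps: float
    pronation_deg: float
    pitch_mean_dps: float
    pronation_class: str
    footstrike_class: str

    def __post_init__(self) -> None:
        if self.pronation_class not in PRONATION_CLASSES:
            raise ValueError(f"bad pronation class {self.pronation_class!r}")
        if self.footstrike_class not in FOOTSTRIKE_CLASSES:
            raise ValueError(f"bad footstrike class {self.footstrike_class!r}")


def extract_step_features(
    recording: ImuRecording,
    timings: list[StepTiming],
    window_ms: float = DEFAULT_WINDOW_MS,
    boundaries: ClassBoundaries | None = None,
) -> list[StepFeature]:
    """Extract rotational-velocity features around each IC.

    Means are taken over the centered window ``[IC - window/2, IC + window/2]``
    (clipped at the bout edges); the pronation angle is the trapezoidal
    integral of roll velocity over the trailing half-window, in degrees.

    Run this on the calibrated (unfiltered) recording: the 5 Hz band-pass
    attenuates the brief roll pulse and would shrink the recovered angle.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    boundaries = boundaries or ClassBoundaries()
    fs = recording.fs_hz
    n = recording.n
    half = int(round(fs * window_ms / 2000.0))
    dt = 1.0 / fs
    features: list[StepFeature] = []
    for timing in timings:
        i = timing.ic.sample_index
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if lo >= n or hi <= 0 or hi - lo < 2:
            warnings.warn(f"step at sample {i}: window outside recording; skipped", stacklevel=2)
            continue
        roll_w = recording.gyr_roll[lo:hi]
        pitch_w = recording.gyr_pitch[lo:hi]
        roll_half = recording.gyr_roll[i : min(n, i + half + 1)]
        pronation = float(np.trapezoid(roll_half, dx=dt)) if roll_half.size >= 2 else 0.0
        roll_mean = float(np.mean(roll_w))
        pitch_mean = float(np.mean(pitch_w))
        features.append(
            StepFeature(
                timing=timing,
                roll_mean_dps=roll_mean,
                pronation_deg=pronation,
                pitch_mean_dps=pitch_mean,
                pronation_class=classify_pronation(pronation, boundaries),
                footstrike_class=classify_footstrike(pitch_mean, boundaries),
            )
        )
    return features


@dataclass(frozen=True)
class BoutResult:
    """Bout-level aggregates: means over steps and majority class labels."""

    steps: tuple[StepFeature, ...]
    n_steps: int
    mean_gct_ms: float | None
    mean_pronation_deg: float | None
    bout_pronation_class: str | None
    bout_footstrike_class: str | None

    def to_dict(self) -> dict:
        return {
            "n_steps": self.n_steps,
            "mean_gct_ms": self.mean_gct_ms,
            "mean_pronation_deg": self.mean_pronation_deg,
            "bout_pronation_class": self.bout_pronation_class,
            "bout_footstrike_class": self.bout_footstrike_class,
        }


def _majority(labels: list[str], severity_order: tuple[str, ...]) -> str:
    counts = {c: labels.count(c) for c in set(labels)}
    best = max(counts.values())
    # among tied classes pick the most severe one
    for c in severity_order:
        if counts.get(c) == best:
            return c
    raise AssertionError("unreachable")


def summarize_bout(steps: list[StepFeature]) -> BoutResult:
    """Aggregate per-step features to a bout summary (majority-vote classes)."""
    if not steps:
        return BoutResult((), 0, None, None, None, None)
    gcts = [s.timing.gct_ms for s in steps if s.timing.gct_ms is not None]
    return BoutResult(
        steps=tuple(steps),
        n_steps=len(steps),
        mean_gct_ms=float(np.mean(gcts)) if gcts else None,
        mean_pronation_deg=float(np.mean([abs(s.pronation_deg) for s in steps])),
        bout_pronation_class=_majority([s.pronation_class for s in steps], _PRONATION_SEVERITY),
        bout_footstrike_class=_majority([s.footstrike_class for s in steps], _FOOTSTRIKE_SEVERITY),
    )


def steps_to_frame(steps: list[StepFeature]) -> pd.DataFrame:
    """Per-step output table (`ic_time_s,gct_ms,pronation_deg,pronation_class,footstrike_class`)."""
    return pd.DataFrame(
        {
            "ic_time_s": [s.timing.ic.time_s for s in steps],
            "gct_ms": [s.timing.gct_ms for s in steps],
            "pronation_deg": [s.pronation_deg for s in steps],
            "pronation_class": [s.pronation_class for s in steps],
            "footstrike_class": [s.footstrike_class for s in steps],
        }
    )


def write_step_csv(steps: list[StepFeature], path: str | Path) -> Path:
    path = Path(path)
    steps_to_frame(steps).to_csv(path, index=False, float_format="%.17g")
    return path


def write_bout_json(bout: BoutResult, path: str | Path, extra: dict | None = None) -> Path:
    path = Path(path)
    payload = bout.to_dict() | (extra or {})
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
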