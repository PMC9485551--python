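"""End-to-end analysis pipeline: calibrate -> filter -> detect -> features.

Candidate events are detected on the band-passed signal and refined against
the calibrated signal (see :mod:`runzc.event_detection`); features are
extracted from the calibrated gyroscope channels so that the roll-angle
integral keeps its physical scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig
from .event_detection import (
    GaitEvent,
    StepTiming,
    detect_initial_contacts,
    pair_steps,
    refine_events,
)
from .gait_features import BoutResult, StepFeature, extract_step_features, summarize_bout
from .imu_io import ImuRecording
from .preprocess import apply_calibration, bandpass_recording, compute_calibration

__all__ = ["GaitAnalysis", "run_gait_analysis"]


@dataclass(frozen=True)
class GaitAnalysis:
    """Everything one bout analysis produces."""

    ics: list[GaitEvent]
    timings: list[StepTiming]
    features: list[StepFeature]
    bout: BoutResult
    config_hash: str


def run_gait_analysis(recording: ImuRecording, config: RunConfig | None = None) -> GaitAnalysis:
    """Analyze one recording with the given (or default) configuration."""
    config = config or RunConfig()

    calibrated = recording
    if config.calibration.window_s and not recording.meta.get("calibrated"):
        profile = compute_calibration(
            recording, (float(recording.t[0]), float(recording.t[0]) + config.calibration.window_s)
        )
        calibrated = apply_calibration(recording, profile)

    filtered = bandpass_recording(calibrated, config.filter.spec())

    tspec = config.detect.spec()
    ics = detect_initial_contacts(filtered, tspec)
    ics = refine_events(
        ics, calibrated.acc_vert, calibrated.fs_hz, radius=config.detect.ic_refine_samples
    )
    timings = pair_steps(
        ics,
        filtered,
        roi_ms=config.detect.roi_ms,
        spec=tspec,
        min_gct_ms=config.detect.min_gct_ms,
        refine_series=calibrated.acc_vert,
        refine_radius=config.detect.fc_refine_samples,
    )
    features = extract_step_features(
        calibrated,
        timings,
        window_ms=config.features.window_ms,
        boundaries=config.features.boundaries(),
    )
    return GaitAnalysis(
        ics=ics,
        timings=timings,
        features=features,
        bout=summarize_bout(features),
        config_hash=config.config_hash(),
    )
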