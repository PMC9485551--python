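"""Static-stance calibration and Butterworth band-pass conditioning.

Runners stand still on the treadmill before each bout; the mean of each
channel over that stance window gives per-channel offsets that absorb local
inclination error and fitting misalignment.  The vertical-acceleration offset
is taken relative to +1 g so that calibrated standing acceleration remains
~1 g.

Detection-relevant channels (``acc_vert``, ``gyr_roll``, ``gyr_pitch``) are
conditioned with a zero-phase Butterworth band-pass so that event latencies
are not shifted; the remaining channels pass through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfilt, sosfiltfilt

from .imu_io import CHANNELS, ImuRecording

__all__ = [
    "CalibrationError",
    "NotStaticError",
    "CalibrationProfile",
    "FilterSpec",
    "compute_calibration",
    "apply_calibration",
    "bandpass_filter",
    "bandpass_recording",
    "FILTERED_CHANNELS",
]

#: Channels the band-pass is applied to; the others pass through untouched.
FILTERED_CHANNELS = ("acc_vert", "gyr_roll", "gyr_pitch")

_ACC_CHANNELS = ("acc_vert", "acc_ap", "acc_ml")
_GYR_CHANNELS = ("gyr_roll", "gyr_pitch", "gyr_yaw")


class CalibrationError(ValueError):
    """Invalid calibration request (window too short, applied twice, ...)."""


class NotStaticError(CalibrationError):
    """The supposedly static stance window contains motion."""


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-channel offsets measured during quiet standing.

    ``acc_offsets['acc_vert']`` is the stance mean minus 1 g; all other
    offsets are plain stance means.  Gyroscope offsets above 10 dps indicate
    the runner was not actually still.
    """

    acc_offsets: dict[str, float]
    gyr_offsets: dict[str, float]
    stance_window: tuple[float, float]

    def __post_init__(self) -> None:
        start, end = self.stance_window
        if end - start < 1.0:
            raise CalibrationError("stance window must be at least 1 s long")
        for ch, off in self.gyr_offsets.items():
            if abs(off) >= 10.0:
                raise NotStaticError(
                    f"gyroscope offset {off:.1f} dps on {ch} — window was not static"
                )

    @classmethod
    def zero(cls) -> "CalibrationProfile":
        return cls(
            acc_offsets={ch: 0.0 for ch in _ACC_CHANNELS},
            gyr_offsets={ch: 0.0 for ch in _GYR_CHANNELS},
            stance_window=(0.0, 1.0),
        )


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    The defaults (4th order, 0.5–5 Hz, zero-phase) keep the step-frequency
    band while removing drift; with ``low_cut_hz = 0`` the filter degenerates
    to a pure low-pass.
    """

    order: int = 4
    low_cut_hz: float = 0.5
    high_cut_hz: float = 5.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.order <= 8:
            raise ValueError(f"order must be in 1..8, got {self.order}")
        if not 0 <= self.low_cut_hz < self.high_cut_hz:
            raise ValueError("need 0 <= low_cut_hz < high_cut_hz")

    def validate_for(self, fs_hz: float) -> None:
        if self.high_cut_hz >= fs_hz / 2:
            raise ValueError(
                f"high_cut_hz {self.high_cut_hz} must be below Nyquist ({fs_hz / 2} Hz)"
            )

    def sos(self, fs_hz: float) -> np.ndarray:
        self.validate_for(fs_hz)
        nyq = fs_hz / 2
        if self.low_cut_hz == 0:
            return butter(self.order, self.high_cut_hz / nyq, btype="low", output="sos")
        return butter(
            self.order,
            [self.low_cut_hz / nyq, self.high_cut_hz / nyq],
            btype="band",
            output="sos",
        )


def compute_calibration(
    recording: ImuRecording, stance_window: tuple[float, float]
) -> CalibrationProfile:
    """Estimate per-channel offsets from a static stance window (seconds).

    Raises :class:`NotStaticError` when any gyroscope channel's standard
    deviation in the window exceeds 20 dps.
    """
    start, end = stance_window
    if end - start < 1.0:
        raise CalibrationError("stance window must be at least 1 s long")
    if start < recording.t[0] - 1e-9 or end > recording.t[-1] + 1e-9:
        raise CalibrationError("stance window extends outside the recording")
    mask = (recording.t >= start) & (recording.t <= end)
    if not mask.any():
        raise CalibrationError("stance window contains no samples")
    for ch in _GYR_CHANNELS:
        if float(np.std(recording.channel(ch)[mask])) > 20.0:
            raise NotStaticError(f"{ch} standard deviation > 20 dps in stance window")
    acc_offsets = {ch: float(np.mean(recording.channel(ch)[mask])) for ch in _ACC_CHANNELS}
    acc_offsets["acc_vert"] -= 1.0  # calibrated standing acc_vert should stay ~1 g
    gyr_offsets = {ch: float(np.mean(recording.channel(ch)[mask])) for ch in _GYR_CHANNELS}
    return CalibrationProfile(acc_offsets, gyr_offsets, (float(start), float(end)))


def apply_calibration(recording: ImuRecording, profile: CalibrationProfile) -> ImuRecording:
    """Subtract stance offsets channel-wise; guarded against double application."""
    if recording.meta.get("calibrated"):
        raise CalibrationError("recording is already calibrated")
    out = recording.copy()
    for ch, off in profile.acc_offsets.items():
        setattr(out, ch, out.channel(ch) - off)
    for ch, off in profile.gyr_offsets.items():
        setattr(out, ch, out.channel(ch) - off)
    out.meta["calibrated"] = True
    out.meta["calibration_window_s"] = profile.stance_window
    return out


def bandpass_filter(series: np.ndarray, spec: FilterSpec, fs_hz: float) -> np.ndarray:
    """Filter a 1-D signal, zero-phase (forward–backward) by default.

    Edges are reflect-padded with ``3 * order`` samples to suppress
    transients, so the series must be longer than ``3 * order``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    padlen = 3 * spec.order
    if x.size <= padlen:
        raise ValueError(
            f"series of length {x.size} is too short to filter; need more than {padlen} samples"
        )
    sos = spec.sos(fs_hz)
    if spec.zero_phase:
        return sosfiltfilt(sos, x, padtype="even", padlen=padlen)
    return sosfilt(sos, x)


def bandpass_recording(
    recording: ImuRecording, spec: FilterSpec | None = None
) -> ImuRecording:
    """Apply :func:`bandpass_filter` to the detection channels of a recording."""
    spec = spec or FilterSpec()
    if recording.meta.get("filtered"):
        warnings.warn("recording already filtered; filtering again", stacklevel=2)
    out = recording.copy()
    for ch in FILTERED_CHANNELS:
        setattr(out, ch, bandpass_filter(recording.channel(ch), spec, recording.fs_hz))
    out.meta["filtered"] = True
    out.meta["filter_spec"] = {
        "order": spec.order,
        "low_cut_hz": spec.low_cut_hz,
        "high_cut_hz": spec.high_cut_hz,
        "zero_phase": spec.zero_phase,
    }
    return out
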