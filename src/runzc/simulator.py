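"""Synthetic foot-mounted-IMU running bouts with exact ground truth.

Each step contributes a stylized vertical-acceleration template: a sharp
positive impact transient at initial contact, a damped post-impact
oscillation ("ringing") whose relative amplitude grows with speed, a negative
unloading trough at final contact and a shallow flight-phase dip, on top of a
1 g baseline plus white noise.  Frontal-plane roll velocity carries a smooth
pulse whose time integral equals the requested pronation angle; sagittal
pitch velocity carries a signed pulse encoding the foot-strike location.

The speed maps for cadence, contact time, impact amplitude, ringing and
noise follow the trends observed on treadmill runners between 8 and 18 km/h;
they are stylizations for testing, not biomechanical models.  Roll noise is
deliberately larger than pitch noise, reproducing the observation that the
horizontal (pronation) plane is the noisier one at speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gait_features import ClassBoundaries, classify_pronation
from .imu_io import (
    ACC_RANGE_G,
    FOOTSTRIKE_CLASSES,
    GYR_RANGE_DPS,
    ImuRecording,
    ReferenceLabels,
    write_labels_csv,
)

__all__ = ["SimulationSpec", "SimulationTruth", "simulate_bout", "export_truth_labels", "truth_to_labels"]

# template geometry (seconds / g / dps); see docs/methods.md for rationale
_IMPACT_SIGMA_S = 0.011
_TROUGH_SIGMA_S = 0.014
_TROUGH_DEPTH_FRAC = 0.35
_RINGING_FREQ_HZ = 12.0
_RINGING_DECAY_S = 0.05
_FLIGHT_DIP_G = 0.10
# pronation develops over the trailing feature half-window (167 ms / 2,
# i.e. 5 sample periods at 60 Hz)
_ROLL_WINDOW_MS = 167.0
_PITCH_PULSE_S = 0.14
_PITCH_AMP_DPS = 250.0
_PAD_S = 1.25  # quiet stance-like padding at both ends


def _cadence_spm(speed_kmh: float) -> float:
    return 160.0 + 2.5 * (speed_kmh - 8.0)


def _gct_ms(speed_kmh: float) -> float:
    return 345.0 - 12.0 * (speed_kmh - 8.0)


def _impact_amp_g(speed_kmh: float) -> float:
    return 3.0 + 0.5 * (speed_kmh - 8.0)


def _ringing_gain(speed_kmh: float) -> float:
    return 0.1 + 0.05 * (speed_kmh - 8.0)


def _noise_acc_g(speed_kmh: float) -> float:
    return 0.02 + 0.01 * (speed_kmh - 8.0)


@dataclass
class SimulationSpec:
    """Conditions of one simulated running bout.

    Fields left at ``None`` are resolved from the speed maps above, so a bare
    ``SimulationSpec(speed_kmh=12)`` reproduces the nominal study conditions
    at that speed.  A fixed seed yields bit-identical output.
    """

    speed_kmh: float = 12.0
    cadence_spm: float | None = None
    gct_ms: float | None = None
    pronation_deg: float = 0.0
    footstrike: str = "heel"
    impact_amp_g: float | None = None
    noise_acc_g: float | None = None
    noise_gyr_roll_dps: float | None = None
    noise_gyr_pitch_dps: float | None = None
    ringing_gain: float | None = None
    n_steps: int = 57
    fs_hz: float = 60.0
    seed: int = 0
    jitter: bool = True

    def __post_init__(self) -> None:
        if not 8.0 <= self.speed_kmh <= 18.0:
            raise ValueError("speed_kmh must be in 8..18")
        if self.cadence_spm is None:
            self.cadence_spm = _cadence_spm(self.speed_kmh)
        if self.gct_ms is None:
            self.gct_ms = _gct_ms(self.speed_kmh)
        if self.impact_amp_g is None:
            self.impact_amp_g = _impact_amp_g(self.speed_kmh)
        if self.ringing_gain is None:
            self.ringing_gain = _ringing_gain(self.speed_kmh)
        if self.noise_acc_g is None:
            self.noise_acc_g = _noise_acc_g(self.speed_kmh)
        if self.noise_gyr_roll_dps is None:
            self.noise_gyr_roll_dps = 150.0 * self.noise_acc_g
        if self.noise_gyr_pitch_dps is None:
            self.noise_gyr_pitch_dps = 50.0 * self.noise_acc_g
        if self.footstrike not in FOOTSTRIKE_CLASSES:
            raise ValueError(f"footstrike must be one of {FOOTSTRIKE_CLASSES}")
        if min(self.cadence_spm, self.gct_ms, self.impact_amp_g, self.fs_hz) <= 0:
            raise ValueError("rates, durations and amplitudes must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if self.noise_acc_g < 0 or self.ringing_gain < 0:
            raise ValueError("noise and ringing must be non-negative")
        step_period_ms = 60000.0 / self.cadence_spm
        if self.gct_ms >= step_period_ms:
            raise ValueError(
                f"infeasible spec: gct_ms {self.gct_ms:.0f} >= step period {step_period_ms:.0f} ms"
            )


@dataclass(frozen=True)
class SimulationTruth:
    """Exact ground-truth event times and per-step parameters."""

    ic_times_s: np.ndarray
    fc_times_s: np.ndarray
    pronation_deg: np.ndarray
    footstrike_class: tuple[str, ...]
    gct_ms: np.ndarray

    def __post_init__(self) -> None:
        n = self.ic_times_s.size
        if not (self.fc_times_s.size == self.pronation_deg.size == self.gct_ms.size == n
                and len(self.footstrike_class) == n):
            raise ValueError("truth fields must have equal length")
        if not np.allclose(self.fc_times_s - self.ic_times_s, self.gct_ms / 1000.0):
            raise ValueError("fc - ic must equal gct_ms/1000 exactly")

    @property
    def n_steps(self) -> int:
        return int(self.ic_times_s.size)


def _hann_pulse(dt: np.ndarray, width_s: float, centered: bool) -> np.ndarray:
    """Unit-amplitude raised-cosine pulse; `centered` spans ±width/2, else [0, width]."""
    if centered:
        m = np.abs(dt) <= width_s / 2
        out = np.zeros_like(dt)
        out[m] = 0.5 * (1 + np.cos(np.pi * dt[m] / (width_s / 2)))
        return out
    m = (dt >= 0) & (dt <= width_s)
    out = np.zeros_like(dt)
    out[m] = 0.5 * (1 - np.cos(2 * np.pi * dt[m] / width_s))
    return out


def simulate_bout(spec: SimulationSpec) -> tuple[ImuRecording, SimulationTruth]:
    """Generate one running bout and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs_hz
    period = 60.0 / spec.cadence_spm
    gct_s = spec.gct_ms / 1000.0

    ic_times = [_PAD_S]
    for _ in range(spec.n_steps - 1):
        jit = rng.uniform(-0.02, 0.02) if spec.jitter else 0.0
        ic_times.append(ic_times[-1] + period * (1.0 + jit))
    ic_times = np.asarray(ic_times)
    fc_times = ic_times + gct_s

    n = int(np.ceil((ic_times[-1] + gct_s + _PAD_S) * fs))
    t = np.arange(n) / fs
    acc_vert = np.ones(n)
    acc_ap = np.zeros(n)
    gyr_roll = np.zeros(n)
    gyr_pitch = np.zeros(n)

    pitch_amp = {"heel": -_PITCH_AMP_DPS, "mid": 0.0, "fore": _PITCH_AMP_DPS}[spec.footstrike]
    for k in range(spec.n_steps):
        ic, fc = ic_times[k], fc_times[k]
        amp = spec.impact_amp_g * (1.0 + (rng.uniform(-0.05, 0.05) if spec.jitter else 0.0))
        dt = t - ic
        acc_vert += amp * np.exp(-0.5 * (dt / _IMPACT_SIGMA_S) ** 2)
        post = dt > 0
        acc_vert[post] += (
            spec.ringing_gain
            * amp
            * np.exp(-dt[post] / _RINGING_DECAY_S)
            * np.sin(2 * np.pi * _RINGING_FREQ_HZ * dt[post])
        )
        acc_vert += -_TROUGH_DEPTH_FRAC * amp * np.exp(-0.5 * ((t - fc) / _TROUGH_SIGMA_S) ** 2)
        nxt = ic_times[k + 1] if k + 1 < spec.n_steps else fc + (period - gct_s)
        flight_mid = (fc + nxt) / 2
        flight_sigma = max((nxt - fc) / 5.0, 1.0 / fs)
        acc_vert += -_FLIGHT_DIP_G * np.exp(-0.5 * ((t - flight_mid) / flight_sigma) ** 2)
        acc_ap += 0.2 * amp * np.exp(-0.5 * (dt / (2 * _IMPACT_SIGMA_S)) ** 2)
        if spec.pronation_deg != 0.0:
            # sample-grid raised-cosine pulse over the trailing half-window,
            # normalized so its trapezoidal time integral is exactly the
            # requested roll angle
            i0 = int(round(ic * fs))
            n_half = int(round(fs * _ROLL_WINDOW_MS / 2000.0))
            k = np.arange(n_half + 1)
            # squared raised cosine: the flat onset/offset makes the integral
            # insensitive to one-sample event-timing errors
            shape = (0.5 * (1 - np.cos(2 * np.pi * k / n_half))) ** 2
            area = np.trapezoid(shape, dx=1.0 / fs)
            sl = slice(i0, min(n, i0 + n_half + 1))
            gyr_roll[sl] += (spec.pronation_deg / area) * shape[: sl.stop - sl.start]
        if pitch_amp != 0.0:
            gyr_pitch += pitch_amp * _hann_pulse(dt, _PITCH_PULSE_S, centered=True)

    acc_vert += rng.normal(0.0, spec.noise_acc_g, n)
    acc_ap += rng.normal(0.0, spec.noise_acc_g, n)
    acc_ml = rng.normal(0.0, spec.noise_acc_g, n)
    gyr_roll += rng.normal(0.0, spec.noise_gyr_roll_dps, n)
    gyr_pitch += rng.normal(0.0, spec.noise_gyr_pitch_dps, n)
    gyr_yaw = rng.normal(0.0, spec.noise_gyr_pitch_dps, n)

    recording = ImuRecording(
        fs_hz=fs,
        acc_vert=np.clip(acc_vert, -ACC_RANGE_G, ACC_RANGE_G),
        acc_ap=np.clip(acc_ap, -ACC_RANGE_G, ACC_RANGE_G),
        acc_ml=np.clip(acc_ml, -ACC_RANGE_G, ACC_RANGE_G),
        gyr_roll=np.clip(gyr_roll, -GYR_RANGE_DPS, GYR_RANGE_DPS),
        gyr_pitch=np.clip(gyr_pitch, -GYR_RANGE_DPS, GYR_RANGE_DPS),
        gyr_yaw=np.clip(gyr_yaw, -GYR_RANGE_DPS, GYR_RANGE_DPS),
        meta={
            "simulated": True,
            "speed_kmh": spec.speed_kmh,
            "seed": spec.seed,
            "n_steps": spec.n_steps,
        },
    )
    truth = SimulationTruth(
        ic_times_s=ic_times,
        fc_times_s=fc_times,
        pronation_deg=np.full(spec.n_steps, float(spec.pronation_deg)),
        footstrike_class=tuple([spec.footstrike] * spec.n_steps),
        gct_ms=np.full(spec.n_steps, float(spec.gct_ms)),
    )
    return recording, truth


def truth_to_labels(
    truth: SimulationTruth, boundaries: ClassBoundaries | None = None, source_fs_hz: float = 60.0
) -> ReferenceLabels:
    """Convert simulation truth into reference labels (classes re-derived
    from the truth pronation angles via the same boundaries used downstream)."""
    boundaries = boundaries or ClassBoundaries()
    return ReferenceLabels(
        ic_time_s=truth.ic_times_s,
        gct_ms=truth.gct_ms,
        pronation_class=[classify_pronation(p, boundaries) for p in truth.pronation_deg],
        footstrike_class=list(truth.footstrike_class),
        source_fs_hz=source_fs_hz,
    )


def export_truth_labels(
    truth: SimulationTruth, path: str | Path, boundaries: ClassBoundaries | None = None
) -> Path:
    """Write the truth as a reference-label CSV in the standard dialect."""
    return write_labels_csv(truth_to_labels(truth, boundaries), path)
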