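"""Reading, writing and axis-mapping of foot-mounted IMU recordings.

The interchange format is plain CSV with the fixed header
``t,acc_vert,acc_ap,acc_ml,gyr_roll,gyr_pitch,gyr_yaw`` — acceleration in g,
angular velocity in deg/s, time in seconds from recording start.  Raw device
files with arbitrary column names and axis orientations are brought into this
anatomical frame through an :class:`AxisMap`.

Anatomical convention: ``acc_vert`` is aligned with gravity during quiet
standing (about +1 g), ``gyr_roll`` is rotation about the anterior–posterior
axis (frontal-plane roll, positive = pronating/inward) and ``gyr_pitch`` is
rotation about the medio-lateral axis (sagittal plane, used for foot-strike
location).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ACC_RANGE_G",
    "GYR_RANGE_DPS",
    "CHANNELS",
    "PRONATION_CLASSES",
    "FOOTSTRIKE_CLASSES",
    "ImuFormatError",
    "EmptyInputError",
    "ImuRecording",
    "AxisMap",
    "ReferenceLabels",
    "read_imu_csv",
    "write_imu_csv",
    "read_labels_csv",
    "write_labels_csv",
    "remap_channels",
]

#: Device measurement ranges (±16 g accelerometer, ±2000 dps gyroscope).
ACC_RANGE_G = 16.0
GYR_RANGE_DPS = 2000.0

CHANNELS = ("acc_vert", "acc_ap", "acc_ml", "gyr_roll", "gyr_pitch", "gyr_yaw")
_ACC_CHANNELS = CHANNELS[:3]
_GYR_CHANNELS = CHANNELS[3:]

PRONATION_CLASSES = ("neutral", "slight", "pronated")
FOOTSTRIKE_CLASSES = ("heel", "mid", "fore")

_LABEL_COLUMNS = ("ic_time_s", "gct_ms", "pronation_class", "footstrike_class")


class ImuFormatError(ValueError):
    """Malformed IMU or label file (missing column, bad cell, bad ordering)."""


class EmptyInputError(ValueError):
    """Input contains no samples / no rows."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class ImuRecording:
    """A calibrated, axis-mapped 6-channel inertial time series.

    Parameters
    ----------
    fs_hz:
        Sampling frequency in Hz (the device polls at 60 Hz).
    acc_vert, acc_ap, acc_ml:
        Acceleration channels in g.
    gyr_roll, gyr_pitch, gyr_yaw:
        Angular-velocity channels in deg/s.
    t:
        Per-sample time in seconds; defaults to ``arange(n)/fs_hz``.
    side:
        Which foot the sensor was mounted on (``left``/``right``/``unknown``).
    meta:
        Free-form provenance (calibration and filter flags live here).
    """

    fs_hz: float
    acc_vert: np.ndarray
    acc_ap: np.ndarray
    acc_ml: np.ndarray
    gyr_roll: np.ndarray
    gyr_pitch: np.ndarray
    gyr_yaw: np.ndarray
    t: np.ndarray | None = None
    side: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        for name in CHANNELS:
            setattr(self, name, _as_float_array(getattr(self, name), name))
        n = self.acc_vert.size
        if n < 1:
            raise EmptyInputError("recording must contain at least one sample")
        for name in CHANNELS:
            if getattr(self, name).size != n:
                raise ValueError(
                    f"channel {name} has length {getattr(self, name).size}, expected {n}"
                )
        if self.t is None:
            self.t = np.arange(n) / self.fs_hz
        else:
            self.t = _as_float_array(self.t, "t")
            if self.t.size != n:
                raise ValueError("t must have the same length as the channels")
            if n > 1:
                dt = np.diff(self.t)
                if np.max(np.abs(dt - 1.0 / self.fs_hz)) >= 1e-6:
                    raise ValueError("t must be uniformly spaced at 1/fs_hz")
        if self.side not in ("left", "right", "unknown"):
            raise ValueError(f"side must be left/right/unknown, got {self.side!r}")
        for name in _ACC_CHANNELS:
            if np.max(np.abs(getattr(self, name)), initial=0.0) > ACC_RANGE_G + 1e-9:
                raise ValueError(f"{name} exceeds the ±{ACC_RANGE_G:g} g device range")
        for name in _GYR_CHANNELS:
            if np.max(np.abs(getattr(self, name)), initial=0.0) > GYR_RANGE_DPS + 1e-9:
                raise ValueError(f"{name} exceeds the ±{GYR_RANGE_DPS:g} dps device range")

    @property
    def n(self) -> int:
        return int(self.acc_vert.size)

    @property
    def duration_s(self) -> float:
        return (self.n - 1) / self.fs_hz

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)

    def copy(self) -> "ImuRecording":
        return replace(
            self,
            **{name: getattr(self, name).copy() for name in CHANNELS},
            t=self.t.copy(),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class AxisMap:
    """Mapping from raw device columns to anatomical channels.

    Which physical gyroscope axis of a talus-mounted sensor corresponds to
    each anatomical plane depends on how the device was fitted, so the map is
    explicit rather than guessed.  Sign flags let any channel be flipped so
    that positive roll means pronation and standing vertical acceleration is
    positive.
    """

    vert_acc_channel: str = "acc_vert"
    roll_gyr_channel: str = "gyr_roll"
    pitch_gyr_channel: str = "gyr_pitch"
    ap_acc_channel: str = "acc_ap"
    ml_acc_channel: str = "acc_ml"
    yaw_gyr_channel: str = "gyr_yaw"
    signs: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        core = (self.vert_acc_channel, self.roll_gyr_channel, self.pitch_gyr_channel)
        if len(set(core)) != 3:
            raise ValueError("vert/roll/pitch raw channels must be distinct")
        for ch, s in self.signs.items():
            if s not in (1, -1):
                raise ValueError(f"sign flag for {ch!r} must be +1 or -1, got {s}")

    @classmethod
    def identity(cls) -> "AxisMap":
        return cls()

    @property
    def raw_to_canonical(self) -> dict[str, str]:
        return {
            self.vert_acc_channel: "acc_vert",
            self.ap_acc_channel: "acc_ap",
            self.ml_acc_channel: "acc_ml",
            self.roll_gyr_channel: "gyr_roll",
            self.pitch_gyr_channel: "gyr_pitch",
            self.yaw_gyr_channel: "gyr_yaw",
        }

    def sign(self, canonical: str) -> int:
        return int(self.signs.get(canonical, 1))


def remap_channels(frame: pd.DataFrame, axis_map: AxisMap) -> pd.DataFrame:
    """Remap raw columns of *frame* to canonical channels, applying signs.

    Applying a map built from a self-inverse column permutation twice (with
    the same sign flags) is the identity.
    """
    out = {}
    for raw, canonical in axis_map.raw_to_canonical.items():
        if raw not in frame.columns:
            raise ImuFormatError(f"mapped column {raw!r} missing from input")
        out[canonical] = axis_map.sign(canonical) * frame[raw].to_numpy(dtype=float)
    return pd.DataFrame(out)


def read_imu_csv(path: str | Path, axis_map: AxisMap | None = None, fs_hz: float = 60.0) -> ImuRecording:
    """Read a raw IMU CSV and return an axis-mapped :class:`ImuRecording`.

    The file must have a header row naming every mapped channel and a purely
    numeric body; row order is preserved and time is rebuilt from ``fs_hz``.
    """
    axis_map = axis_map or AxisMap.identity()
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if raw.shape[0] == 0:
        raise EmptyInputError(f"{path} has a header but no samples")
    for col in axis_map.raw_to_canonical:
        if col not in raw.columns:
            raise ImuFormatError(f"mapped column {col!r} missing from {path}")
    numeric = {}
    for col in axis_map.raw_to_canonical:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.index[vals.isna() & raw[col].notna()]
        if len(bad) or vals.isna().any():
            row = int((bad if len(bad) else vals.index[vals.isna()])[0]) + 2  # 1-based + header
        if vals.isna().any():
            raise ImuFormatError(f"non-numeric value in column {col!r} at line {row} of {path}")
        numeric[col] = vals.to_numpy(dtype=float)
    frame = pd.DataFrame(numeric)
    mapped = remap_channels(frame, axis_map)
    return ImuRecording(
        fs_hz=fs_hz,
        meta={"source": str(path)},
        **{ch: mapped[ch].to_numpy() for ch in CHANNELS},
    )


def write_imu_csv(recording: ImuRecording, path: str | Path) -> Path:
    """Write *recording* with the fixed canonical header at full precision."""
    if recording.n == 0:  # unreachable through the public constructor
        raise EmptyInputError("cannot write an empty recording")
    path = Path(path)
    frame = pd.DataFrame({"t": recording.t} | {ch: recording.channel(ch) for ch in CHANNELS})
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


@dataclass
class ReferenceLabels:
    """Per-step reference labels emulating motion-capture ground truth.

    One record per step: initial-contact time, ground contact time in ms and
    the categorical pronation / foot-strike labels used in the field
    (neutral/slight/pronated; heel/mid/fore).
    """

    ic_time_s: np.ndarray
    gct_ms: np.ndarray
    pronation_class: list[str]
    footstrike_class: list[str]
    source_fs_hz: float = 200.0

    def __post_init__(self) -> None:
        self.ic_time_s = _as_float_array(self.ic_time_s, "ic_time_s")
        self.gct_ms = _as_float_array(self.gct_ms, "gct_ms")
        self.pronation_class = list(self.pronation_class)
        self.footstrike_class = list(self.footstrike_class)
        n = self.ic_time_s.size
        if not (self.gct_ms.size == len(self.pronation_class) == len(self.footstrike_class) == n):
            raise ValueError("all label columns must have equal length")
        if n > 1 and not np.all(np.diff(self.ic_time_s) > 0):
            raise ImuFormatError("ic_time_s must be strictly increasing")
        if n and np.any(self.gct_ms <= 0):
            raise ValueError("gct_ms must be positive")
        for c in self.pronation_class:
            if c not in PRONATION_CLASSES:
                raise ImuFormatError(
                    f"unknown pronation class {c!r}; allowed: {PRONATION_CLASSES}"
                )
        for c in self.footstrike_class:
            if c not in FOOTSTRIKE_CLASSES:
                raise ImuFormatError(
                    f"unknown footstrike class {c!r}; allowed: {FOOTSTRIKE_CLASSES}"
                )
        if self.source_fs_hz <= 0:
            raise ValueError("source_fs_hz must be positive")

    @property
    def n_steps(self) -> int:
        return int(self.ic_time_s.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ic_time_s": self.ic_time_s,
                "gct_ms": self.gct_ms,
                "pronation_class": self.pronation_class,
                "footstrike_class": self.footstrike_class,
            }
        )


def read_labels_csv(path: str | Path, source_fs_hz: float = 200.0) -> ReferenceLabels:
    """Read and validate a reference label CSV (closed class vocabularies)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    for col in _LABEL_COLUMNS:
        if col not in frame.columns:
            raise ImuFormatError(f"label column {col!r} missing from {path}")
    if frame.shape[0] == 0:
        return ReferenceLabels(
            ic_time_s=np.empty(0),
            gct_ms=np.empty(0),
            pronation_class=[],
            footstrike_class=[],
            source_fs_hz=source_fs_hz,
        )
    return ReferenceLabels(
        ic_time_s=frame["ic_time_s"].to_numpy(dtype=float),
        gct_ms=frame["gct_ms"].to_numpy(dtype=float),
        pronation_class=[str(c) for c in frame["pronation_class"]],
        footstrike_class=[str(c) for c in frame["footstrike_class"]],
        source_fs_hz=source_fs_hz,
    )


def write_labels_csv(labels: ReferenceLabels, path: str | Path) -> Path:
    path = Path(path)
    labels.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path
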