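"""Zero-crossing gradient-maxima gait-event detection.

Initial contact (IC) appears as a sharp positive peak in vertical
acceleration; it is found by locating sign changes (+ to -) in the first
difference of the signal — a gradient zero-crossing at a local maximum — and
keeping only peaks that exceed a dynamic threshold tied to the local signal
maxima.  A cadence-derived refractory pass removes the false positives that
post-impact ringing would otherwise contribute.

Final contact (FC) is the inverse peak inside a region of interest after the
IC; ground contact time (GCT) is the elapsed time between the two, reported
in integer milliseconds.

Detection is coarse-to-fine: candidates come from the band-pass-filtered
signal (robust to noise), and :func:`refine_events` snaps each candidate to
the local extremum of the calibrated, unfiltered signal, whose transients
carry the exact timing that the 5 Hz low-pass unavoidably blurs at 60 Hz.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .imu_io import ImuRecording

__all__ = [
    "InsufficientDataError",
    "GaitEvent",
    "ThresholdSpec",
    "StepTiming",
    "dynamic_threshold",
    "zc_gradient_peaks",
    "detect_initial_contacts",
    "detect_final_contact",
    "refine_events",
    "samples_to_ms",
    "pair_steps",
]

logger = logging.getLogger(__name__)

#: Default region of interest after an IC in which the FC must fall (ms).
DEFAULT_ROI_MS = 500.0
#: Physiological floor on ground contact time: the FC search starts this long
#: after the IC so the impact transient cannot masquerade as an inverse peak.
DEFAULT_MIN_GCT_MS = 120.0


class InsufficientDataError(ValueError):
    """Recording too short to contain the strides needed for detection."""


@dataclass(frozen=True)
class GaitEvent:
    """A detected initial (IC) or final (FC) contact."""

    sample_index: int
    time_s: float
    kind: str  # "IC" or "FC"
    peak_value: float

    def __post_init__(self) -> None:
        if self.kind not in ("IC", "FC"):
            raise ValueError(f"kind must be IC or FC, got {self.kind!r}")
        if self.sample_index < 0:
            raise ValueError("sample_index must be non-negative")


def _event(series: np.ndarray, index: int, fs_hz: float, kind: str) -> GaitEvent:
    return GaitEvent(int(index), index / fs_hz, kind, float(series[index]))


@dataclass(frozen=True)
class ThresholdSpec:
    """Dynamic-threshold and refractory configuration.

    ``maxima_fraction`` is the fraction of the local (rolling-window) signal
    maximum a peak must exceed; ``refractory_fraction`` expresses the minimum
    inter-peak gap as a fraction of the median inter-peak interval observed in
    a first, refractory-free pass (``None`` disables the refractory pass).
    """

    maxima_fraction: float = 0.4
    maxima_window_s: float = 2.5
    refractory_fraction: float | None = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.maxima_fraction < 1:
            raise ValueError("maxima_fraction must be in (0, 1)")
        if self.maxima_window_s <= 0:
            raise ValueError("maxima_window_s must be positive")
        if self.refractory_fraction is not None and not 0 < self.refractory_fraction < 1:
            raise ValueError("refractory_fraction must be in (0, 1) or None")


@dataclass(frozen=True)
class StepTiming:
    """Per-step IC/FC pairing; FC and GCT are absent when no inverse peak passed."""

    ic: GaitEvent
    fc: GaitEvent | None = None
    gct_ms: int | None = None

    def __post_init__(self) -> None:
        if (self.fc is None) != (self.gct_ms is None):
            raise ValueError("gct_ms must be present exactly when fc is present")
        if self.fc is not None:
            if self.fc.sample_index <= self.ic.sample_index:
                raise ValueError("fc must come after ic")
            if self.fc.time_s - self.ic.time_s > DEFAULT_ROI_MS / 1000.0 + 1e-9:
                raise ValueError("fc outside the 500 ms region of interest")


def dynamic_threshold(
    series: np.ndarray, fs_hz: float, spec: ThresholdSpec | None = None
) -> np.ndarray:
    """Per-sample threshold: ``maxima_fraction`` x rolling max of ``|series|``.

    The window is centered, ``maxima_window_s`` long, and clipped at the bout
    edges (the maximum is taken over the available samples only).
    """
    spec = spec or ThresholdSpec()
    x = np.abs(np.asarray(series, dtype=float))
    if x.size == 0:
        raise ValueError("series must be non-empty")
    half = int(round(spec.maxima_window_s * fs_hz / 2))
    # with mode="nearest" the replicated edge value is already inside the
    # shrunk window, so this equals the clipped-window maximum exactly
    rolling_max = maximum_filter1d(x, size=2 * half + 1, mode="nearest")
    return spec.maxima_fraction * rolling_max


def _plateau_first_maxima(x: np.ndarray) -> np.ndarray:
    """Indices where the first difference crosses + to -; plateaus yield their first index."""
    d = np.diff(x)
    s = np.sign(d)
    # backward-fill zeros so a plateau inherits the sign of what follows it
    rev = s[::-1]
    idx = np.where(rev != 0, np.arange(rev.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, rev[np.maximum(idx, 0)], 0.0)[::-1]
    return np.where((s[:-1] > 0) & (filled[1:] < 0))[0] + 1


def _greedy_refractory(candidates: list[int], values: np.ndarray, gap: float) -> list[int]:
    """Left-to-right acceptance with a minimum gap; on conflict keep the larger peak."""
    accepted: list[int] = []
    for i in candidates:
        if accepted and i - accepted[-1] < gap:
            if values[i] > values[accepted[-1]]:
                accepted[-1] = i
        else:
            accepted.append(i)
    return accepted


def zc_gradient_peaks(
    series: np.ndarray, fs_hz: float, spec: ThresholdSpec | None = None
) -> list[int]:
    """Zero-crossing gradient-maxima peak indices of a 1-D signal.

    A sample qualifies when the gradient changes sign + to - there (first
    index of a plateau), its value strictly exceeds the dynamic threshold,
    and — in a second pass — it respects the refractory gap derived from the
    median inter-peak interval of the first pass.
    """
    spec = spec or ThresholdSpec()
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("series must contain at least 3 samples")
    thr = dynamic_threshold(x, fs_hz, spec)
    cand = [int(i) for i in _plateau_first_maxima(x) if x[i] > thr[i]]
    if spec.refractory_fraction is not None and len(cand) >= 2:
        gap = spec.refractory_fraction * float(np.median(np.diff(cand)))
        cand = _greedy_refractory(cand, x, gap)
    return cand


def detect_initial_contacts(
    recording: ImuRecording, spec: ThresholdSpec | None = None
) -> list[GaitEvent]:
    """Detect ICs as ZC gradient-maxima peaks of vertical acceleration."""
    if recording.n < 1.5 * recording.fs_hz:
        raise InsufficientDataError(
            "recording shorter than ~2 strides (1.5 s); cannot detect gait events"
        )
    if not recording.meta.get("calibrated"):
        logger.warning("detecting on an uncalibrated recording")
    if not recording.meta.get("filtered"):
        logger.warning("detecting on an unfiltered recording")
    idx = zc_gradient_peaks(recording.acc_vert, recording.fs_hz, spec)
    return [_event(recording.acc_vert, i, recording.fs_hz, "IC") for i in idx]


def refine_events(
    events: list[GaitEvent],
    series: np.ndarray,
    fs_hz: float,
    radius: int = 2,
    mode: str = "max",
) -> list[GaitEvent]:
    """Snap each event to the local extremum of *series* within ``radius`` samples.

    Used to transfer candidate events detected on the band-passed signal onto
    the calibrated signal, recovering the timing precision the low-pass blurs.
    Events that collapse onto the same sample are merged (first kept).
    """
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    x = np.asarray(series, dtype=float)
    out: list[GaitEvent] = []
    seen: set[int] = set()
    for ev in sorted(events, key=lambda e: e.sample_index):
        lo = max(0, ev.sample_index - radius)
        hi = min(x.size, ev.sample_index + radius + 1)
        w = x[lo:hi]
        j = lo + int(np.argmin(w) if mode == "min" else np.argmax(w))
        if j in seen:
            continue
        seen.add(j)
        out.append(_event(x, j, fs_hz, ev.kind))
    return out


def detect_final_contact(
    recording: ImuRecording,
    ic: GaitEvent,
    roi_ms: float = DEFAULT_ROI_MS,
    spec: ThresholdSpec | None = None,
    next_ic_index: int | None = None,
    min_gct_ms: float = DEFAULT_MIN_GCT_MS,
    refine_series: np.ndarray | None = None,
    refine_radius: int = 6,
    search_margin: int = 3,
) -> GaitEvent | None:
    """Find the final contact as the inverse peak after *ic*, or ``None``.

    The ZC gradient-maxima scan runs on the negated vertical acceleration
    restricted to ``(ic + min_gct_ms, ic + roi_ms]``; the lower edge is a
    physiological minimum contact time keeping the impact transient out of
    the search.  The threshold is referenced to the maximum of the negated
    segment (the inverse-peak amplitude scale) because inside the ROI the
    largest absolute values belong to the decaying impact, which would
    otherwise mask the unloading trough at slow speeds.

    Candidate search may look ``search_margin`` samples past the next IC (the
    filtered trough lobe leans early/left), but the returned event is always
    strictly before the next IC and within the ROI.  When *refine_series* is
    given every accepted candidate is refined to the deepest sample of that
    series and the overall deepest refined trough wins; otherwise the
    largest-magnitude filtered candidate wins.
    """
    spec = spec or ThresholdSpec()
    fs = recording.fs_hz
    n = recording.n
    x = recording.acc_vert
    i = ic.sample_index
    if i >= n - 1:
        logger.info("IC at the final sample; no room for a final contact")
        return None
    roi = int(round(roi_ms / 1000.0 * fs))
    lo_off = int(round(min_gct_ms / 1000.0 * fs))
    hard_end = min(n, i + roi + 1)  # FC must satisfy fc - ic <= roi
    if next_ic_index is not None:
        hard_end = min(hard_end, next_ic_index)  # and fall strictly before the next IC
    start = i + lo_off
    search_end = min(n, i + roi + 1)
    if next_ic_index is not None:
        search_end = min(search_end, next_ic_index + search_margin)
    if search_end - start < 3:
        return None
    seg = -x[start:search_end]
    cand = [int(c) for c in _plateau_first_maxima(seg)]
    top = float(seg.max())
    cand = [c for c in cand if seg[c] > spec.maxima_fraction * top]
    if not cand:
        return None
    if refine_series is None:
        best = start + max(cand, key=lambda c: seg[c])
        if best >= hard_end:
            return None
        return _event(x, best, fs, "FC")
    r = np.asarray(refine_series, dtype=float)
    best: int | None = None
    for c in cand:
        j = start + c
        lo = max(start, j - refine_radius)
        hi = min(hard_end, j + refine_radius + 1)
        if lo >= hi:
            continue
        rj = lo + int(np.argmin(r[lo:hi]))
        if best is None or r[rj] < r[best]:
            best = rj
    if best is None:
        return None
    return GaitEvent(int(best), best / fs, "FC", float(r[best]))


def samples_to_ms(n_samples: int, fs_hz: float) -> int:
    """Convert a sample count to integer milliseconds (round half away from zero).

    Standardizes contact times across sampling resolutions, e.g. 38 samples
    at 200 Hz and 11 samples at 60 Hz become 190 ms and 183 ms.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    return int(math.floor(n_samples / fs_hz * 1000.0 + 0.5))


def pair_steps(
    ics: list[GaitEvent],
    recording: ImuRecording,
    roi_ms: float = DEFAULT_ROI_MS,
    spec: ThresholdSpec | None = None,
    min_gct_ms: float = DEFAULT_MIN_GCT_MS,
    refine_series: np.ndarray | None = None,
    refine_radius: int = 6,
) -> list[StepTiming]:
    """Pair every IC with its final contact; unpaired ICs carry no GCT.

    The FC search region is additionally truncated at the next IC to prevent
    cross-step pairing.
    """
    timings: list[StepTiming] = []
    for k, ic in enumerate(ics):
        nxt = ics[k + 1].sample_index if k + 1 < len(ics) else None
        fc = detect_final_contact(
            recording,
            ic,
            roi_ms=roi_ms,
            spec=spec,
            next_ic_index=nxt,
            min_gct_ms=min_gct_ms,
            refine_series=refine_series,
            refine_radius=refine_radius,
        )
        if fc is None:
            timings.append(StepTiming(ic=ic))
        else:
            gct = samples_to_ms(fc.sample_index - ic.sample_index, recording.fs_hz)
            timings.append(StepTiming(ic=ic, fc=fc, gct_ms=gct))
    return timings
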