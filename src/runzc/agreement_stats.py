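"""Method-agreement statistics between the IMU algorithm and a reference.

Absolute agreement is quantified with ICC(2,1) — two-way random effects,
absolute agreement, single measures — banded on the conventional scale
(poor < 0.500, moderate 0.500–0.750, good 0.750–0.900, excellent > 0.900),
together with Bland–Altman bias and 95% limits of agreement and plain mean
errors.  A windowed noise-to-signal ratio around initial contacts quantifies
the post-impact noise that degrades feature extraction at higher speeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

from .event_detection import GaitEvent
from .imu_io import FOOTSTRIKE_CLASSES, PRONATION_CLASSES, ImuRecording

__all__ = [
    "PairedMeasurements",
    "BlandAltman",
    "AgreementReport",
    "icc_2_1",
    "classify_icc",
    "bland_altman",
    "mean_errors",
    "agreement_report",
    "noise_to_signal",
    "ordinal_codes",
    "bland_altman_plot",
]

ICC_BANDS = ("poor", "moderate", "good", "excellent")


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired algorithm (a) and reference (b) values, same length and units."""

    a: np.ndarray
    b: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.a.ndim != 1 or self.b.ndim != 1:
            raise ValueError("paired measurements must be one-dimensional")
        if self.a.size != self.b.size:
            raise ValueError("a and b must have equal length")
        if self.a.size == 0:
            raise ValueError("paired measurements must be non-empty")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("paired measurements must be finite (drop missing pairs upstream)")

    @property
    def n(self) -> int:
        return int(self.a.size)


def icc_2_1(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    With n subjects and k = 2 raters the estimate is
    ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))`` where MSR, MSC and
    MSE are the rows (subjects), columns (raters) and residual mean squares of
    the two-way ANOVA.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    n = a.size
    if n < 3:
        raise ValueError("ICC(2,1) needs at least 3 paired observations")
    x = np.column_stack([a, b])
    k = 2
    grand = x.mean()
    if np.allclose(x, grand):
        warnings.warn("all values identical; ICC defined as 1.0", stacklevel=2)
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        warnings.warn("zero denominator in ICC; returning 1.0", stacklevel=2)
        return 1.0
    return float((msr - mse) / denom)


def classify_icc(icc: float) -> str:
    """Band an ICC on the conventional agreement scale.

    Boundary values 0.500 and 0.750 go to the higher band; 0.900 stays
    "good" because the excellent band is strictly above 0.900.
    """
    if not -1.0 - 1e-12 <= icc <= 1.0 + 1e-12:
        raise ValueError(f"ICC must lie in [-1, 1], got {icc}")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd: float


def bland_altman(pairs: PairedMeasurements) -> BlandAltman:
    """Bias (mean difference) and 95% limits of agreement (bias ± 1.96 SD)."""
    if pairs.n < 2:
        raise ValueError("Bland–Altman needs at least 2 pairs")
    d = pairs.a - pairs.b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd)


def mean_errors(pairs: PairedMeasurements) -> tuple[float, float | None]:
    """Mean absolute error and percentage error of the means.

    ``mean_error_pct = 100 |mean(a) - mean(b)| / mean(b)``; ``None`` with a
    warning when ``mean(b)`` is zero.
    """
    abs_err = float(np.mean(np.abs(pairs.a - pairs.b)))
    mb = float(np.mean(pairs.b))
    if mb == 0:
        warnings.warn("mean of reference is zero; percentage error undefined", stacklevel=2)
        return abs_err, None
    pct = 100.0 * abs(float(np.mean(pairs.a)) - mb) / mb
    return abs_err, pct


@dataclass(frozen=True)
class AgreementReport:
    """ICC + band, mean errors and Bland–Altman summary for one comparison."""

    icc_value: float
    icc_band: str
    mean_error_abs: float
    mean_error_pct: float | None
    bland_altman: BlandAltman
    n: int
    units: str = ""

    def to_dict(self) -> dict:
        return {
            "icc_value": self.icc_value,
            "icc_band": self.icc_band,
            "mean_error_abs": self.mean_error_abs,
            "mean_error_pct": self.mean_error_pct,
            "bland_altman": {
                "bias": self.bland_altman.bias,
                "loa_low": self.bland_altman.loa_low,
                "loa_high": self.bland_altman.loa_high,
            },
            "n": self.n,
            "units": self.units,
        }


def agreement_report(pairs: PairedMeasurements) -> AgreementReport:
    icc = icc_2_1(pairs.a, pairs.b)
    abs_err, pct = mean_errors(pairs)
    return AgreementReport(
        icc_value=icc,
        icc_band=classify_icc(icc),
        mean_error_abs=abs_err,
        mean_error_pct=pct,
        bland_altman=bland_altman(pairs),
        n=pairs.n,
        units=pairs.units,
    )


def ordinal_codes(labels: list[str], kind: str) -> np.ndarray:
    """Encode class labels as ordinal codes (neutral/heel=0 ... pronated/fore=2).

    This is an interpretation: agreement on categorical outcomes is reported
    on these codes because no canonical numeric scale exists for them.
    """
    vocab = PRONATION_CLASSES if kind == "pronation" else FOOTSTRIKE_CLASSES
    try:
        return np.array([vocab.index(c) for c in labels], dtype=float)
    except ValueError as exc:
        raise ValueError(f"label outside vocabulary {vocab}: {exc}") from None


def noise_to_signal(
    recording: ImuRecording,
    ics: list[GaitEvent],
    window_ms: float = 167.0,
    channel: str = "gyr_roll",
    smooth_cut_hz: float = 5.0,
) -> float:
    """Mean noise-to-signal ratio (%) in windows centered on each IC.

    The channel is split into a smooth component (zero-phase low-pass at
    ``smooth_cut_hz``, computed over the whole channel so short windows carry
    no filter edge transients) and a residual; per window the ratio is
    ``100 * RMS(residual) / RMS(segment)``, averaged across ICs.
    """
    if not ics:
        raise ValueError("need at least one IC")
    if channel not in ("gyr_roll", "gyr_pitch"):
        raise ValueError("channel must be gyr_roll or gyr_pitch")
    x = recording.channel(channel)
    fs = recording.fs_hz
    half = int(round(fs * window_ms / 2000.0))
    b, a = butter(2, smooth_cut_hz / (fs / 2), btype="low")
    smooth = filtfilt(b, a, x, padlen=min(3 * max(len(a), len(b)), x.size - 1))
    resid = x - smooth
    ratios = []
    for ev in ics:
        lo = max(0, ev.sample_index - half)
        hi = min(recording.n, ev.sample_index + half + 1)
        seg = x[lo:hi]
        if seg.size < 5:
            continue
        rms_seg = float(np.sqrt(np.mean(seg**2)))
        if rms_seg == 0:
            ratios.append(0.0)
            continue
        ratios.append(100.0 * float(np.sqrt(np.mean(resid[lo:hi] ** 2))) / rms_seg)
    if not ratios:
        raise ValueError("no usable IC windows")
    return float(np.mean(ratios))


def bland_altman_plot(pairs: PairedMeasurements, path: str | Path, title: str = "") -> Path:
    """Save a Bland–Altman plot (means vs differences with bias and limits)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(pairs)
    means = (pairs.a + pairs.b) / 2
    diffs = pairs.a - pairs.b
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=12, alpha=0.7)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel(f"mean of methods {pairs.units}".strip())
    ax.set_ylabel(f"difference (a - b) {pairs.units}".strip())
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
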