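"""Scoring detected events and features against simulator ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gait_features import StepFeature
from .simulator import SimulationTruth

__all__ = ["DetectionScores", "match_events", "detection_scores", "StepRecovery", "score_steps"]


@dataclass(frozen=True)
class DetectionScores:
    precision: float
    recall: float
    f1: float
    n_detected: int
    n_truth: int
    n_matched: int


def match_events(
    detected_s: np.ndarray, truth_s: np.ndarray, tol_s: float
) -> list[tuple[int, int]]:
    """Greedily match each truth event to the nearest unused detection within tol.

    Returns (detected_index, truth_index) pairs; truth events are processed in
    chronological order.
    """
    detected_s = np.asarray(detected_s, dtype=float)
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for j, tt in enumerate(np.asarray(truth_s, dtype=float)):
        best, best_d = -1, tol_s
        for i, dt in enumerate(detected_s):
            if i in used:
                continue
            d = abs(dt - tt)
            if d <= best_d:
                best, best_d = i, d
        if best >= 0:
            used.add(best)
            pairs.append((best, j))
    return pairs


def detection_scores(detected_s, truth_s, tol_s: float) -> DetectionScores:
    pairs = match_events(detected_s, truth_s, tol_s)
    nd, nt, nm = len(detected_s), len(truth_s), len(pairs)
    precision = nm / nd if nd else 0.0
    recall = nm / nt if nt else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return DetectionScores(precision, recall, f1, nd, nt, nm)


@dataclass(frozen=True)
class StepRecovery:
    """Per-bout recovery metrics over truth-matched steps."""

    ic: DetectionScores
    fc: DetectionScores
    gct_abs_err_ms: np.ndarray  # one entry per matched step with a recovered GCT
    pronation_accuracy: float
    footstrike_accuracy: float
    n_matched: int


def score_steps(
    features: list[StepFeature],
    truth: SimulationTruth,
    fs_hz: float,
    tol_samples: float = 3.0,
    boundaries=None,
) -> StepRecovery:
    """Match detected steps to truth by IC time and score timing + classes."""
    from .gait_features import ClassBoundaries, classify_pronation

    boundaries = boundaries or ClassBoundaries()
    tol_s = tol_samples / fs_hz
    det_ic = np.array([f.timing.ic.time_s for f in features])
    ic_scores = detection_scores(det_ic, truth.ic_times_s, tol_s)
    det_fc = np.array(
        [f.timing.fc.time_s for f in features if f.timing.fc is not None]
    )
    fc_scores = detection_scores(det_fc, truth.fc_times_s, tol_s)

    pairs = match_events(det_ic, truth.ic_times_s, tol_s)
    gct_errs, pron_ok, strike_ok = [], 0, 0
    for i, j in pairs:
        f = features[i]
        if f.timing.gct_ms is not None:
            gct_errs.append(abs(f.timing.gct_ms - truth.gct_ms[j]))
        truth_pron_class = classify_pronation(truth.pronation_deg[j], boundaries)
        pron_ok += f.pronation_class == truth_pron_class
        strike_ok += f.footstrike_class == truth.footstrike_class[j]
    n = len(pairs)
    return StepRecovery(
        ic=ic_scores,
        fc=fc_scores,
        gct_abs_err_ms=np.asarray(gct_errs, dtype=float),
        pronation_accuracy=pron_ok / n if n else 0.0,
        footstrike_accuracy=strike_ok / n if n else 0.0,
        n_matched=n,
    )
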