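"""Evaluation metrics: threshold metrics, rank AUC, and the MODS utility score.

The utility score credits alarms raised in a window around each patient's
onset with a piecewise-linear per-hour reward, penalizes false alarms and
missed detections, and is normalized so a silent policy scores 0 and the
optimal alarm policy scores exactly 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class UtilityParams:
    """Shape of the per-hour alarm utility around a MODS onset.

    An alarm earns a reward rising 0 to 1 over ``[onset - early_bound,
    onset + peak]`` and falling back to 0 over ``(onset + peak,
    onset + late_bound]``; outside that window it counts as a false alarm
    (``u_fp`` per hour).  Staying silent inside the window ramps linearly
    from 0 down to ``u_fn_floor`` at ``onset + late_bound``; outside the
    window silence is neutral.  Non-MODS hours: alarm ``u_fp``, silence
    ``u_tn``.
    """

    early_bound: int = 12
    peak: int = 0
    late_bound: int = 3
    u_fp: float = -0.05
    u_fn_floor: float = -2.0
    u_tn: float = 0.0

    def __post_init__(self) -> None:
        if self.early_bound <= 0:
            raise MetricError("early_bound must be positive")
        if self.late_bound < self.peak:
            raise MetricError("late_bound must be >= peak")
        if self.u_fp > 0 or self.u_fn_floor > 0:
            raise MetricError("penalties u_fp and u_fn_floor must be <= 0")


@dataclass(frozen=True)
class PatientAlarms:
    """One patient's hourly alarm trace for utility evaluation."""

    patient_id: str
    hours: tuple[int, ...]
    alarms: tuple[bool, ...]
    onset: Optional[int]

    def __post_init__(self) -> None:
        if len(self.hours) != len(self.alarms):
            raise MetricError("hours and alarms must have equal length")


@dataclass
class MetricsReport:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    yi: float
    utility_score: Optional[float]
    threshold: float
    n_entries: int
    n_patients: int

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def binary_metrics(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, accuracy, Youden index) at a threshold."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise MetricError("labels and probabilities must align")
    pos, neg = int((y == 1).sum()), int((y == 0).sum())
    if pos == 0 or neg == 0:
        raise MetricError("both classes required for sensitivity/specificity")
    pred = p >= threshold
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    sensitivity = tp / pos
    specificity = tn / neg
    accuracy = (tp + tn) / len(y)
    yi = sensitivity + specificity - 1.0
    return sensitivity, specificity, accuracy, yi


def auc(labels: Sequence[int], probabilities: Sequence[float]) -> float:
    """Rank-based AUC (probability of correct pairwise ordering, ties 1/2)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise MetricError("both classes required for AUC")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def yi_maximizing_threshold(labels: Sequence[int], probabilities: Sequence[float]) -> float:
    """Probability cutoff maximizing sensitivity + specificity - 1."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    candidates = np.unique(p)
    best_t, best_yi = 0.5, -np.inf
    for t in candidates:
        try:
            _, _, _, yi = binary_metrics(y, p, threshold=float(t))
        except MetricError:
            continue
        if yi > best_yi:
            best_yi, best_t = yi, float(t)
    return best_t


# ---------------------------------------------------------------------------
# Utility score
# ---------------------------------------------------------------------------

def _alarm_utility(t: int, onset: int, prm: UtilityParams) -> float:
    lo, hi = onset - prm.early_bound, onset + prm.late_bound
    if t < lo or t > hi:
        return prm.u_fp
    peak_t = onset + prm.peak
    if t <= peak_t:
        return (t - lo) / (peak_t - lo) if peak_t > lo else 1.0
    return (hi - t) / (hi - peak_t) if hi > peak_t else 1.0


def _silence_utility(t: int, onset: int, prm: UtilityParams) -> float:
    # the missed-detection ramp applies only inside the reward window;
    # outside it silence is neutral, which keeps the in-window alarm
    # policy optimal (and the normalized score <= 1 for every policy)
    lo, hi = onset - prm.early_bound, onset + prm.late_bound
    if t < lo or t > hi:
        return 0.0
    return prm.u_fn_floor * (t - lo) / (hi - lo) if hi > lo else prm.u_fn_floor


def _raw_utility(patient: PatientAlarms, prm: UtilityParams) -> float:
    total = 0.0
    for t, alarm in zip(patient.hours, patient.alarms):
        if patient.onset is None:
            total += prm.u_fp if alarm else prm.u_tn
        elif alarm:
            total += _alarm_utility(t, patient.onset, prm)
        else:
            total += _silence_utility(t, patient.onset, prm)
    return total


def _optimal_alarms(patient: PatientAlarms, prm: UtilityParams) -> PatientAlarms:
    if patient.onset is None:
        alarms = tuple(False for _ in patient.hours)
    else:
        lo, hi = patient.onset - prm.early_bound, patient.onset + prm.late_bound
        alarms = tuple(lo <= t <= hi for t in patient.hours)
    return PatientAlarms(patient.patient_id, patient.hours, alarms, patient.onset)


def utility_score(
    per_patient: Iterable[PatientAlarms],
    params: Optional[UtilityParams] = None,
) -> float:
    """Normalized cohort utility: silent policy -> 0, optimal policy -> 1.

    ``(U - U_silent) / (U_optimal - U_silent)`` with anchors recomputed on
    the evaluated cohort.  If the cohort contains no onset (the anchors
    coincide) the un-normalized difference ``U - U_silent`` is returned.
    """
    params = params or UtilityParams()
    patients = list(per_patient)
    if not patients:
        raise MetricError("empty cohort")
    u = sum(_raw_utility(p, params) for p in patients)
    silent = [
        PatientAlarms(p.patient_id, p.hours, tuple(False for _ in p.hours), p.onset)
        for p in patients
    ]
    u_silent = sum(_raw_utility(p, params) for p in silent)
    u_opt = sum(_raw_utility(_optimal_alarms(p, params), params) for p in patients)
    denom = u_opt - u_silent
    if denom == 0:
        return u - u_silent
    return (u - u_silent) / denom


def alarms_from_predictions(
    patient_ids: Sequence[str],
    hours: Sequence[int],
    probabilities: Sequence[float],
    onsets: dict,
    threshold: float = 0.5,
) -> list[PatientAlarms]:
    """Group per-entry predictions into per-patient alarm traces."""
    by_patient: dict[str, list[tuple[int, bool]]] = {}
    for pid, h, p in zip(patient_ids, hours, probabilities):
        by_patient.setdefault(str(pid), []).append((int(h), p >= threshold))
    out = []
    for pid, rows in by_patient.items():
        rows.sort()
        out.append(
            PatientAlarms(
                patient_id=pid,
                hours=tuple(h for h, _ in rows),
                alarms=tuple(a for _, a in rows),
                onset=onsets.get(pid),
            )
        )
    return out


def evaluate_predictions(
    labels: Sequence[int],
    probabilities: Sequence[float],
    patient_ids: Sequence[str],
    hours: Sequence[int],
    onsets: dict,
    threshold: float = 0.5,
    utility_params: Optional[UtilityParams] = None,
) -> MetricsReport:
    """Full report over an entry table with known per-patient onsets."""
    sens, spec, acc, yi = binary_metrics(labels, probabilities, threshold)
    area = auc(labels, probabilities)
    traces = alarms_from_predictions(patient_ids, hours, probabilities, onsets, threshold)
    util = utility_score(traces, utility_params)
    return MetricsReport(
        auc=area,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        yi=yi,
        utility_score=util,
        threshold=threshold,
        n_entries=len(list(labels)),
        n_patients=len(traces),
    )
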