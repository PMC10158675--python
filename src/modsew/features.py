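"""Cohort filtering, hourly windowing, feature extraction and labeling.

Every patient-hour becomes one entry with exactly 37 features: mean/max/min
of the eight clinical variables over the half-open window ``(hour-1, hour]``
(24 features), the elapsed ICU hour, six current organ sub-scores, and six
trailing-24-hour rolling maxima of those sub-scores.  Clinical aggregates
are forward- then backward-filled across hours; organ sub-scores are never
imputed — they are recomputed from the filled clinical values.

Labels are binary: 1 iff a known onset occurs within ``horizon`` hours of
the entry (post-onset hours included; set ``truncate_at_onset`` to drop
them).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import (
    HEALTHY_REFERENCE,
    HIGHER_WORSE,
    ORGAN_AGGREGATES,
    ORGANS,
    VARIABLES,
    MODSCriterion,
    OrganScores,
    ScoreTable,
    detect_mods,
)
from .synthetic import PatientStay


class FeatureError(ValueError):
    pass


#: camelCase token per variable used in feature names.
VAR_TOKEN: Mapping[str, str] = {
    "heart_rate": "Hr",
    "dopamine": "Dopamine",
    "oxygenation_index": "Oi",
    "gcs": "Gcs",
    "lactate": "Lactate",
    "creatinine": "Creatinine",
    "bilirubin": "Bilirubin",
    "platelets": "Platelet",
}

#: Feature name of each organ's current sub-score (the neurologic score is
#: conventionally named after the GCS that drives it).
CURRENT_SCORE_FEATURE: Mapping[str, str] = {
    "cardiovascular": "currentCardiovascularMods",
    "respiratory": "currentRespiratoryMods",
    "renal": "currentRenalMods",
    "neurologic": "currentGcsMods",
    "hepatic": "currentHepaticMods",
    "hematologic": "currentHematologicMods",
}

ROLLING_SCORE_FEATURE: Mapping[str, str] = {
    "cardiovascular": "cardiovascular24HoursMods",
    "respiratory": "respiratory24HoursMods",
    "renal": "renal24HoursMods",
    "neurologic": "gcs24HoursMods",
    "hepatic": "hepatic24HoursMods",
    "hematologic": "hematologic24HoursMods",
}

_STATS = ("mean", "max", "min")


def _stat_feature(stat: str, variable: str) -> str:
    return f"current{stat.capitalize()}{VAR_TOKEN[variable]}"


#: The 37 feature names in canonical column order.
FEATURE_NAMES: tuple[str, ...] = (
    ("currentHour",)
    + tuple(_stat_feature(stat, var) for var in VARIABLES for stat in _STATS)
    + tuple(CURRENT_SCORE_FEATURE[o] for o in ORGANS)
    + tuple(ROLLING_SCORE_FEATURE[o] for o in ORGANS)
)

ROLLING_WINDOW_HOURS = 24
ENTRY_COLUMNS = ("patient_id", "hour", "label") + FEATURE_NAMES


# ---------------------------------------------------------------------------
# Cohort filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortFilter:
    min_age: float = 65.0
    min_los: float = 24.0  # exclusive
    max_missing_rate: float = 0.30  # exclusive
    first_stay_only: bool = True
    missing_mode: str = "variable"  # or "hourly"

    def __post_init__(self) -> None:
        if self.min_age <= 0 or self.min_los <= 0:
            raise FeatureError("filter thresholds must be positive")
        if not 0.0 < self.max_missing_rate < 1.0:
            raise FeatureError("max_missing_rate must be in (0, 1)")
        if self.missing_mode not in ("variable", "hourly"):
            raise FeatureError("missing_mode must be 'variable' or 'hourly'")


def missing_rate(stay: PatientStay, mode: str = "variable") -> float:
    """Fraction of missing data for a stay.

    ``variable`` mode: fraction of the eight variables with zero
    observations over the whole stay.  ``hourly`` mode: mean over variables
    of the fraction of hourly windows containing no observation.
    """
    observed = {o.variable for o in stay.observations}
    if mode == "variable":
        return 1.0 - len(observed & set(VARIABLES)) / len(VARIABLES)
    n_hours = max(stay.length_hours, 1)
    frac_missing = []
    for var in VARIABLES:
        hours = {
            max(1, math.ceil(o.time_offset))
            for o in stay.observations
            if o.variable == var
        }
        frac_missing.append(1.0 - len(hours) / n_hours)
    return float(np.mean(frac_missing))


def filter_cohort(
    cohort: Iterable[PatientStay],
    cohort_filter: Optional[CohortFilter] = None,
) -> tuple[list[PatientStay], list[tuple[str, str]]]:
    """Apply the inclusion criteria; return kept stays + exclusion log."""
    f = cohort_filter or CohortFilter()
    kept: list[PatientStay] = []
    log: list[tuple[str, str]] = []
    for stay in cohort:
        if stay.age < f.min_age:
            log.append((stay.patient_id, "age"))
        elif stay.length_hours <= f.min_los:
            log.append((stay.patient_id, "length_of_stay"))
        elif f.first_stay_only and not stay.first_icu_stay:
            log.append((stay.patient_id, "not_first_stay"))
        elif missing_rate(stay, f.missing_mode) >= f.max_missing_rate:
            log.append((stay.patient_id, "missingness"))
        else:
            kept.append(stay)
    return kept, log


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_clinical(series: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Forward-fill then backward-fill a time-ordered value series.

    Returns the filled array and a flag set when the series was entirely
    missing (in which case it is returned unfilled and should count toward
    the stay's missing rate instead of being imputed).
    """
    s = pd.Series(np.asarray(series, dtype=float))
    if s.isna().all():
        return s.to_numpy(), True
    return s.ffill().bfill().to_numpy(), False


def _score_column(values: np.ndarray, variable: str, table: ScoreTable) -> np.ndarray:
    bands = table.bands[variable]
    ts = np.asarray(bands.thresholds, dtype=float)
    v = np.asarray(values, dtype=float)[:, None]
    if bands.direction == HIGHER_WORSE:
        return (v > ts[None, :]).sum(axis=1)
    return (v <= ts[None, :]).sum(axis=1)


# ---------------------------------------------------------------------------
# Hourly frame construction
# ---------------------------------------------------------------------------

def hourly_frame(
    stay: PatientStay,
    table: Optional[ScoreTable] = None,
    fallback_healthy: bool = True,
) -> pd.DataFrame:
    """Per-hour frame with filled aggregates, organ scores and rolling maxima.

    Index: hour 1..T.  Columns: ``mean_<var>``, ``max_<var>``, ``min_<var>``
    for each variable, ``score_<organ>`` and ``rolling_<organ>``.

    Variables with no observations at all are filled with the healthy
    reference value when ``fallback_healthy`` (stays violating the
    missing-rate filter should have been excluded upstream).
    """
    table = table or ScoreTable.default()
    if not stay.observations:
        raise FeatureError(f"stay {stay.patient_id} has no observations")
    n_hours = stay.length_hours
    rows = pd.DataFrame(
        {
            "hour": [max(1, math.ceil(o.time_offset)) for o in stay.observations],
            "variable": [o.variable for o in stay.observations],
            "value": [o.value for o in stay.observations],
        }
    )
    agg = (
        rows.groupby(["variable", "hour"])["value"]
        .agg(["mean", "max", "min"])
        .reset_index()
    )
    index = pd.RangeIndex(1, n_hours + 1, name="hour")
    frame = pd.DataFrame(index=index)
    for var in VARIABLES:
        sub = agg[agg["variable"] == var].set_index("hour")
        for stat in _STATS:
            col = f"{stat}_{var}"
            series = sub[stat].reindex(index) if len(sub) else pd.Series(np.nan, index=index)
            filled, all_missing = impute_clinical(series.to_numpy())
            if all_missing:
                if not fallback_healthy:
                    raise FeatureError(
                        f"variable {var!r} entirely missing for stay {stay.patient_id}"
                    )
                filled = np.full(len(index), HEALTHY_REFERENCE[var])
            frame[col] = filled

    # organ sub-scores from filled aggregates (never imputed directly)
    for organ, sources in ORGAN_AGGREGATES.items():
        component_scores = [
            _score_column(frame[f"{stat}_{var}"].to_numpy(), var, table)
            for stat, var in sources
        ]
        frame[f"score_{organ}"] = np.max(component_scores, axis=0)
    for organ in ORGANS:
        frame[f"rolling_{organ}"] = (
            frame[f"score_{organ}"].rolling(ROLLING_WINDOW_HOURS, min_periods=1).max().astype(int)
        )
    return frame


def score_stay(
    stay: PatientStay, table: Optional[ScoreTable] = None
) -> list[OrganScores]:
    """Hourly OrganScores for a stay (hours 1..T), via the filled frame."""
    frame = hourly_frame(stay, table)
    return [
        OrganScores(**{organ: int(row[f"score_{organ}"]) for organ in ORGANS})
        for _, row in frame.iterrows()
    ]


def detect_stay_onset(
    stay: PatientStay,
    table: Optional[ScoreTable] = None,
    criterion: Optional[MODSCriterion] = None,
) -> Optional[int]:
    """Convenience: score a stay hour by hour and detect the MODS onset."""
    return detect_mods(score_stay(stay, table), criterion)


# ---------------------------------------------------------------------------
# Feature extraction and labeling
# ---------------------------------------------------------------------------

def _features_from_frame(frame: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=frame.index)
    out["currentHour"] = frame.index.to_numpy(dtype=float)
    for var in VARIABLES:
        for stat in _STATS:
            out[_stat_feature(stat, var)] = frame[f"{stat}_{var}"].to_numpy()
    for organ in ORGANS:
        out[CURRENT_SCORE_FEATURE[organ]] = frame[f"score_{organ}"].to_numpy(dtype=float)
        out[ROLLING_SCORE_FEATURE[organ]] = frame[f"rolling_{organ}"].to_numpy(dtype=float)
    return out[list(FEATURE_NAMES)]


def extract_features(
    stay: PatientStay, hour: int, table: Optional[ScoreTable] = None
) -> pd.Series:
    """The 37-feature vector of one patient-hour."""
    frame = hourly_frame(stay, table)
    if hour < 1 or hour > len(frame):
        raise FeatureError(f"hour {hour} outside stay of {len(frame)} hours")
    return _features_from_frame(frame).loc[hour]


def label_entries(
    n_hours: int,
    onset: Optional[int],
    horizon: int = 12,
    truncate_at_onset: bool = False,
) -> pd.Series:
    """Binary label per hour 1..n_hours: onset within ``horizon`` hours.

    ``label(t) = 1`` iff an onset exists and ``onset <= t + horizon``;
    post-onset hours stay positive.  With ``truncate_at_onset`` hours after
    the onset are dropped from the index.
    """
    if horizon < 1:
        raise FeatureError("horizon must be >= 1")
    hours = pd.RangeIndex(1, n_hours + 1, name="hour")
    if onset is None:
        labels = pd.Series(0, index=hours, dtype=int)
    else:
        labels = pd.Series((onset <= hours.to_numpy() + horizon).astype(int), index=hours)
        if truncate_at_onset:
            labels = labels[labels.index <= onset]
    return labels


def featurize_stay(
    stay: PatientStay,
    onset: Optional[int],
    table: Optional[ScoreTable] = None,
    horizon: int = 12,
    truncate_at_onset: bool = False,
) -> pd.DataFrame:
    """All hourly entries for one stay: patient_id, hour, label, 37 features."""
    frame = hourly_frame(stay, table)
    feats = _features_from_frame(frame)
    labels = label_entries(len(frame), onset, horizon, truncate_at_onset)
    feats = feats.loc[labels.index]
    out = feats.reset_index()
    out.insert(0, "patient_id", stay.patient_id)
    out.insert(2, "label", labels.to_numpy())
    return out[list(ENTRY_COLUMNS)]


def build_entries(
    cohort: Iterable[PatientStay],
    truth: Mapping[str, Optional[int]],
    table: Optional[ScoreTable] = None,
    horizon: int = 12,
    truncate_at_onset: bool = False,
) -> pd.DataFrame:
    """Entry table for a whole cohort."""
    parts = [
        featurize_stay(stay, truth.get(stay.patient_id), table, horizon, truncate_at_onset)
        for stay in cohort
    ]
    if not parts:
        return pd.DataFrame(columns=list(ENTRY_COLUMNS))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-feature mean/sd fitted on the training split only."""

    mu: pd.Series
    sigma: pd.Series

    def to_json(self, path) -> None:
        payload = {
            name: {"mu": float(self.mu[name]), "sigma": float(self.sigma[name])}
            for name in self.mu.index
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormalizationParams":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        names = list(payload)
        mu = pd.Series({n: payload[n]["mu"] for n in names})
        sigma = pd.Series({n: payload[n]["sigma"] for n in names})
        return cls(mu=mu, sigma=sigma)


def fit_normalizer(entries: pd.DataFrame, feature_names: Sequence[str] = FEATURE_NAMES) -> NormalizationParams:
    X = entries[list(feature_names)]
    return NormalizationParams(mu=X.mean(), sigma=X.std(ddof=0))


def apply_normalizer(entries: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    names = list(params.mu.index)
    missing = set(names) - set(entries.columns)
    if missing:
        raise FeatureError(f"entries missing features: {sorted(missing)}")
    out = entries.copy()
    sigma = params.sigma.replace(0.0, 1.0)  # sd 0 -> center only
    out[names] = (entries[names] - params.mu) / sigma
    return out


# ---------------------------------------------------------------------------
# Patient-level split
# ---------------------------------------------------------------------------

def split_by_patient(
    entries: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify_onsets: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split entries into train/validation with no patient on both sides.

    With ``stratify_onsets`` patients are partitioned separately within the
    has-positive-entries and all-negative groups, so small validation sets
    keep both classes when possible.
    """
    patients = entries["patient_id"].unique()
    if len(patients) < 2:
        raise FeatureError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    if stratify_onsets:
        has_pos = entries.groupby("patient_id")["label"].max()
        pos_ids = [p for p in patients if has_pos[p] == 1]
        neg_ids = [p for p in patients if has_pos[p] == 0]
        train_ids: set = set()
        for group in (pos_ids, neg_ids):
            if not group:
                continue
            order = rng.permutation(len(group))
            n_grp = int(round(train_fraction * len(group)))
            n_grp = min(max(n_grp, 1), max(len(group) - 1, 1))
            train_ids.update(group[i] for i in order[:n_grp])
        # keep both sides non-empty
        if len(train_ids) == len(patients):
            train_ids.discard(next(iter(train_ids)))
    else:
        order = rng.permutation(len(patients))
        train_ids = set(patients[order[:n_train]])
    train_mask = entries["patient_id"].isin(train_ids)
    return (
        entries[train_mask].reset_index(drop=True),
        entries[~train_mask].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Entries persistence
# ---------------------------------------------------------------------------

def write_entries(entries: pd.DataFrame, path) -> None:
    entries[list(ENTRY_COLUMNS)].to_csv(path, index=False)


def read_entries(path) -> pd.DataFrame:
    entries = pd.read_csv(path)
    missing = set(ENTRY_COLUMNS) - set(entries.columns)
    if missing:
        raise FeatureError(f"entries file missing columns: {sorted(missing)}")
    return entries[list(ENTRY_COLUMNS)]
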