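"""Per-organ 0-4 dysfunction sub-scores and MODS onset detection.

Each of the eight clinical variables maps to an integer severity score in
0..4 through an ordered band table; six organ systems are scored from the
hourly worst-case aggregates, with the cardiovascular score taken as the
maximum of the dopamine-, lactate- and heart-rate-mapped scores.  A MODS
onset is the first hour at which at least ``organs_required`` organs reach
a sub-score of at least ``dysfunction_threshold``.

The default band cut-points are configurable placeholders (the reference
cut-point table is not published in a machine-readable form); replace them
by loading a YAML file with :meth:`ScoreTable.from_yaml`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

#: Canonical clinical variable identifiers, stable order.
VARIABLES: tuple[str, ...] = (
    "heart_rate",
    "dopamine",
    "oxygenation_index",
    "gcs",
    "lactate",
    "creatinine",
    "bilirubin",
    "platelets",
)

#: Organ systems, stable order.
ORGANS: tuple[str, ...] = (
    "cardiovascular",
    "respiratory",
    "renal",
    "neurologic",
    "hepatic",
    "hematologic",
)

#: Healthy reference values (score 0 under the default table).
HEALTHY_REFERENCE: Mapping[str, float] = {
    "heart_rate": 80.0,
    "dopamine": 0.0,
    "oxygenation_index": 400.0,
    "gcs": 15.0,
    "lactate": 1.0,
    "creatinine": 80.0,
    "bilirubin": 10.0,
    "platelets": 250.0,
}

#: Aggregate (over the hourly window) that governs each organ's sub-score.
ORGAN_AGGREGATES: Mapping[str, tuple[tuple[str, str], ...]] = {
    "cardiovascular": (("max", "dopamine"), ("max", "lactate"), ("max", "heart_rate")),
    "respiratory": (("min", "oxygenation_index"),),
    "renal": (("max", "creatinine"),),
    "neurologic": (("min", "gcs"),),
    "hepatic": (("max", "bilirubin"),),
    "hematologic": (("min", "platelets"),),
}

HIGHER_WORSE = "higher_worse"
LOWER_WORSE = "lower_worse"


class ScoringError(ValueError):
    """Raised on invalid scoring inputs or malformed band tables."""


@dataclass(frozen=True)
class VariableBands:
    """Severity bands for one variable.

    ``higher_worse``: thresholds ascending; score = number of thresholds
    strictly below the value (band s is (t_{s-1}, t_s], closed on the
    healthy side).  ``lower_worse``: thresholds descending; score = number
    of thresholds at or above the value (band s is [t_s, t_{s-1})).
    """

    direction: str
    thresholds: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER_WORSE, LOWER_WORSE):
            raise ScoringError(f"unknown direction {self.direction!r}")
        ts = self.thresholds
        if len(ts) != 4:
            raise ScoringError("exactly 4 thresholds required (5 bands)")
        ordered = all(a < b for a, b in zip(ts, ts[1:]))
        if self.direction == HIGHER_WORSE and not ordered:
            raise ScoringError("higher_worse thresholds must be strictly ascending")
        if self.direction == LOWER_WORSE and not all(a > b for a, b in zip(ts, ts[1:])):
            raise ScoringError("lower_worse thresholds must be strictly descending")

    def score(self, value: float) -> int:
        if not math.isfinite(value):
            raise ScoringError(f"non-finite value {value!r}")
        if self.direction == HIGHER_WORSE:
            return sum(1 for t in self.thresholds if value > t)
        return sum(1 for t in self.thresholds if value <= t)


_DEFAULT_BANDS: dict[str, VariableBands] = {
    "heart_rate": VariableBands(HIGHER_WORSE, (100, 120, 140, 160)),
    "dopamine": VariableBands(HIGHER_WORSE, (0, 5, 10, 15)),
    "lactate": VariableBands(HIGHER_WORSE, (2, 3.5, 5, 8)),
    "creatinine": VariableBands(HIGHER_WORSE, (100, 200, 350, 500)),
    "bilirubin": VariableBands(HIGHER_WORSE, (20, 60, 120, 240)),
    "oxygenation_index": VariableBands(LOWER_WORSE, (300, 225, 150, 75)),
    "gcs": VariableBands(LOWER_WORSE, (14, 12, 9, 6)),
    "platelets": VariableBands(LOWER_WORSE, (120, 80, 50, 20)),
}


@dataclass(frozen=True)
class ScoreTable:
    """Band tables for all scored variables."""

    bands: Mapping[str, VariableBands] = field(
        default_factory=lambda: dict(_DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        missing = set(VARIABLES) - set(self.bands)
        if missing:
            raise ScoringError(f"score table missing variables: {sorted(missing)}")

    @classmethod
    def default(cls) -> "ScoreTable":
        return cls()

    @classmethod
    def from_yaml(cls, path) -> "ScoreTable":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: Mapping) -> "ScoreTable":
        bands = {}
        for var, entry in raw.items():
            bands[var] = VariableBands(
                direction=entry["direction"],
                thresholds=tuple(float(t) for t in entry["thresholds"]),
            )
        return cls(bands=bands)

    def to_yaml(self, path) -> None:
        raw = {
            var: {
                "direction": vb.direction,
                "thresholds": [float(t) for t in vb.thresholds],
            }
            for var, vb in self.bands.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def default_score_table_path() -> str:
    """Path to the shipped default band-table YAML."""
    return str(resources.files("modsew").joinpath("data/score_table.default.yaml"))


@dataclass(frozen=True)
class OrganScores:
    """Six per-organ sub-scores, each an integer in 0..4."""

    cardiovascular: int
    respiratory: int
    renal: int
    neurologic: int
    hepatic: int
    hematologic: int

    def __post_init__(self) -> None:
        for organ in ORGANS:
            s = getattr(self, organ)
            if not (isinstance(s, (int,)) and 0 <= s <= 4):
                raise ScoringError(f"{organ} sub-score {s!r} outside 0..4")

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, organ) for organ in ORGANS)

    def n_dysfunctional(self, threshold: int) -> int:
        return sum(1 for s in self.as_tuple() if s >= threshold)


@dataclass(frozen=True)
class MODSCriterion:
    """Onset rule: at least ``organs_required`` organs at or above
    ``dysfunction_threshold``."""

    dysfunction_threshold: int = 2
    organs_required: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.dysfunction_threshold <= 4:
            raise ScoringError("dysfunction_threshold must be in 1..4")
        if not 1 <= self.organs_required <= 6:
            raise ScoringError("organs_required must be in 1..6")


def score_variable(value: float, variable: str, table: Optional[ScoreTable] = None) -> int:
    """Map one clinical value to its 0..4 severity score."""
    table = table or ScoreTable.default()
    if variable not in table.bands:
        raise ScoringError(f"unknown variable {variable!r}")
    return table.bands[variable].score(float(value))


def organ_scores(aggregates: Mapping[str, float], table: Optional[ScoreTable] = None) -> OrganScores:
    """Score all six organs from hourly worst-case aggregates.

    ``aggregates`` keys are ``"<stat>_<variable>"`` (e.g. ``max_creatinine``,
    ``min_gcs``).  The cardiovascular score is the maximum of the dopamine-,
    lactate- and heart-rate-mapped scores.
    """
    table = table or ScoreTable.default()
    out: dict[str, int] = {}
    for organ, sources in ORGAN_AGGREGATES.items():
        scores = []
        for stat, var in sources:
            key = f"{stat}_{var}"
            if key not in aggregates:
                raise ScoringError(f"missing aggregate {key!r} for organ {organ!r}")
            scores.append(score_variable(aggregates[key], var, table))
        out[organ] = max(scores)
    return OrganScores(**out)


def detect_mods(
    hourly_scores: Sequence[OrganScores],
    criterion: Optional[MODSCriterion] = None,
) -> Optional[int]:
    """First hour (1-based) at which the MODS criterion holds, else None."""
    if len(hourly_scores) == 0:
        raise ScoringError("empty hourly score sequence")
    criterion = criterion or MODSCriterion()
    for hour, scores in enumerate(hourly_scores, start=1):
        if scores.n_dysfunctional(criterion.dysfunction_threshold) >= criterion.organs_required:
            return hour
    return None
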