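"""Seeded synthetic ICU cohorts with analytically known MODS onsets.

Baseline physiology is stationary noise confined to the score-0 band of
every variable; a deterioration episode ramps the governing variable of
each targeted organ toward (but below) the dysfunction band and then steps
into the target band exactly at the onset hour, so that hourly scoring
recovers the injected onset exactly.

Observation times follow exponential inter-arrival sampling thinned by a
per-variable missing rate; every variable gets an anchor observation near
admission so back-fill imputation cannot leak deterioration backwards.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .scoring import (
    HEALTHY_REFERENCE,
    HIGHER_WORSE,
    ORGAN_AGGREGATES,
    ORGANS,
    VARIABLES,
    MODSCriterion,
    ScoreTable,
    score_variable,
)


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the field."""


class ParseError(ValueError):
    """Malformed observation file; message carries the line number."""


OBS_HEADER = ("patient_id", "age", "first_icu_stay", "time_offset_hours", "variable", "value")

#: Variable manipulated to drive each organ's sub-score.
ORGAN_DRIVER: Mapping[str, str] = {
    "cardiovascular": "lactate",
    "respiratory": "oxygenation_index",
    "renal": "creatinine",
    "neurologic": "gcs",
    "hepatic": "bilirubin",
    "hematologic": "platelets",
}

# Baseline samplers stay strictly inside the default score-0 band.
_BASELINE = {
    "heart_rate": (80.0, 7.0, 55.0, 99.0),
    "dopamine": (0.0, 0.0, 0.0, 0.0),
    "oxygenation_index": (400.0, 35.0, 310.0, 520.0),
    "gcs": (15.0, 0.0, 15.0, 15.0),
    "lactate": (1.0, 0.3, 0.2, 1.9),
    "creatinine": (80.0, 8.0, 55.0, 99.0),
    "bilirubin": (10.0, 3.0, 2.0, 19.0),
    "platelets": (250.0, 35.0, 130.0, 450.0),
}

_INT_VARIABLES = {"gcs"}


@dataclass(frozen=True)
class Observation:
    time_offset: float  # hours since admission
    variable: str
    value: float


@dataclass
class PatientStay:
    """One ICU stay: irregular observations plus the ground-truth onset."""

    patient_id: str
    age: float
    first_icu_stay: bool
    observations: list[Observation]
    true_onset_hour: Optional[int] = None

    @property
    def length_hours(self) -> int:
        if not self.observations:
            return 0
        return max(1, int(math.ceil(max(o.time_offset for o in self.observations))))

    def sorted_observations(self) -> list[Observation]:
        return sorted(self.observations, key=lambda o: (o.time_offset, o.variable))


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 100
    mean_los_hours: float = 72.0
    age_range: tuple[float, float] = (55.0, 90.0)
    mods_prevalence: float = 0.3
    onset_window: tuple[int, int] = (30, 60)
    missing_rate: float = 0.10
    sampling_interval: float = 45.0  # mean minutes between observations
    seed: int = 0
    under_65_fraction: Optional[float] = None  # exercise age filtering
    drop_variable_prob: float = 0.0  # chance a variable is never observed

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if self.mean_los_hours <= 24:
            raise ConfigError("mean_los_hours must exceed 24")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigError("age_range must be an increasing (low, high) pair")
        if not 0.0 <= self.mods_prevalence <= 1.0:
            raise ConfigError("mods_prevalence must be in [0, 1]")
        if not (0 < self.onset_window[0] <= self.onset_window[1]):
            raise ConfigError("onset_window must satisfy 0 < min <= max")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.sampling_interval <= 0:
            raise ConfigError("sampling_interval must be positive")
        if self.under_65_fraction is not None and not 0.0 <= self.under_65_fraction <= 1.0:
            raise ConfigError("under_65_fraction must be in [0, 1]")
        if not 0.0 <= self.drop_variable_prob < 1.0:
            raise ConfigError("drop_variable_prob must be in [0, 1)")


@dataclass(frozen=True)
class DeteriorationProfile:
    """Target sub-score per organ, reached exactly at the onset hour."""

    targets: Mapping[str, int] = field(
        default_factory=lambda: {"neurologic": 4, "renal": 3}
    )
    ramp_hours: int = 6

    def validate(self) -> None:
        for organ, score in self.targets.items():
            if organ not in ORGANS:
                raise ConfigError(f"unknown organ {organ!r} in profile")
            if not 0 <= score <= 4:
                raise ConfigError(f"target score {score!r} outside 0..4")
        if self.ramp_hours < 1:
            raise ConfigError("ramp_hours must be >= 1")


def value_for_score(variable: str, score: int, table: Optional[ScoreTable] = None) -> float:
    """A representative value of ``variable`` mapping to exactly ``score``."""
    table = table or ScoreTable.default()
    bands = table.bands[variable]
    ts = bands.thresholds
    if bands.direction == HIGHER_WORSE:
        if score == 0:
            v = ts[0] - max(1.0, abs(ts[0]) * 0.2) if ts[0] > 0 else 0.0
        elif score == 4:
            v = ts[3] + max(2.0, abs(ts[3]) * 0.3)
        else:
            v = (ts[score - 1] + ts[score]) / 2.0
    else:  # lower_worse, thresholds descending
        if score == 0:
            v = ts[0] + max(1.0, abs(ts[0]) * 0.2)
        elif score == 4:
            v = ts[3] * 0.5
        else:
            v = (ts[score] + ts[score - 1]) / 2.0
    if variable in _INT_VARIABLES:
        v = float(round(v))
    assert score_variable(v, variable, table) == score, (variable, score, v)
    return v


def _baseline_value(rng: np.random.Generator, variable: str) -> float:
    mean, sd, lo, hi = _BASELINE[variable]
    v = mean if sd == 0 else float(np.clip(rng.normal(mean, sd), lo, hi))
    if variable in _INT_VARIABLES:
        v = float(round(v))
    return v


def _sample_times(rng: np.random.Generator, los: float, mean_interval_hours: float) -> list[float]:
    times, t = [], 0.0
    while True:
        t += float(rng.exponential(mean_interval_hours))
        if t >= los:
            return times
        times.append(t)


def inject_deterioration(
    stay: PatientStay,
    onset_hour: int,
    profile: Optional[DeteriorationProfile] = None,
    table: Optional[ScoreTable] = None,
    criterion: Optional[MODSCriterion] = None,
) -> PatientStay:
    """Return a copy of ``stay`` deteriorating so scoring detects ``onset_hour``.

    For each targeted organ, its driver variable ramps (piecewise-linearly,
    one observation per hour) from the healthy reference toward the worst
    value still below the dysfunction threshold, then steps to the target
    band in the window ``(onset_hour - 1, onset_hour]`` and stays there.
    """
    profile = profile or DeteriorationProfile()
    profile.validate()
    table = table or ScoreTable.default()
    criterion = criterion or MODSCriterion()
    n_hours = stay.length_hours
    if onset_hour < 1 or onset_hour > n_hours:
        raise ConfigError(
            f"onset_hour {onset_hour} outside stay of {n_hours} hours"
        )

    drivers = {ORGAN_DRIVER[organ]: target for organ, target in profile.targets.items()}
    ramp_start = max(0, onset_hour - 1 - profile.ramp_hours)

    kept = [
        o
        for o in stay.observations
        if o.variable not in drivers or o.time_offset <= ramp_start
    ]
    new_obs: list[Observation] = []
    for variable, target in drivers.items():
        healthy = HEALTHY_REFERENCE[variable]
        # worst value that still scores below the dysfunction threshold
        cap_score = min(max(criterion.dysfunction_threshold - 1, 0), max(target - 1, 0))
        cap_value = value_for_score(variable, cap_score, table)
        target_value = value_for_score(variable, target, table)
        # anchor a healthy value so back-fill cannot pull severity earlier
        new_obs.append(Observation(min(0.05, ramp_start + 0.01), variable, healthy))
        ramp_span = max(onset_hour - 1 - ramp_start, 1)
        for h in range(ramp_start + 1, onset_hour):
            frac = (h - ramp_start) / ramp_span
            v = healthy + frac * (cap_value - healthy)
            if variable in _INT_VARIABLES:
                v = float(round(v))
                if score_variable(v, variable, table) > cap_score:
                    v = cap_value
            new_obs.append(Observation(h - 0.5, variable, v))
        for h in range(onset_hour, n_hours + 1):
            new_obs.append(Observation(min(h - 0.5, n_hours - 1e-6), variable, target_value))

    obs = sorted(kept + new_obs, key=lambda o: (o.time_offset, o.variable))
    return replace(stay, observations=obs, true_onset_hour=onset_hour)


def _simulate_stay(
    rng: np.random.Generator,
    cfg: SimConfig,
    patient_id: str,
    table: ScoreTable,
    criterion: MODSCriterion,
) -> PatientStay:
    is_mods = bool(rng.random() < cfg.mods_prevalence)
    onset: Optional[int] = None
    if is_mods:
        onset = int(rng.integers(cfg.onset_window[0], cfg.onset_window[1] + 1))

    los = 24.0 + float(rng.exponential(max(cfg.mean_los_hours - 24.0, 1.0)))
    los = max(los, 26.0)
    if onset is not None:
        los = max(los, onset + 6.0)

    if cfg.under_65_fraction is not None and rng.random() < cfg.under_65_fraction:
        age = float(rng.uniform(min(cfg.age_range[0], 45.0), 64.99))
    else:
        age = float(rng.uniform(cfg.age_range[0], cfg.age_range[1]))
    first_stay = bool(rng.random() < 0.9)

    dropped = {
        v for v in VARIABLES if cfg.drop_variable_prob and rng.random() < cfg.drop_variable_prob
    }
    interval_h = cfg.sampling_interval / 60.0
    obs: list[Observation] = []
    for variable in VARIABLES:
        if variable in dropped:
            continue
        obs.append(Observation(0.05, variable, _baseline_value(rng, variable)))
        for t in _sample_times(rng, los, interval_h):
            if rng.random() < cfg.missing_rate:
                continue
            obs.append(Observation(t, variable, _baseline_value(rng, variable)))

    stay = PatientStay(
        patient_id=patient_id,
        age=age,
        first_icu_stay=first_stay,
        observations=sorted(obs, key=lambda o: (o.time_offset, o.variable)),
        true_onset_hour=None,
    )
    if onset is not None:
        stay = inject_deterioration(stay, onset, table=table, criterion=criterion)
    return stay


def simulate_cohort(
    cfg: SimConfig,
    table: Optional[ScoreTable] = None,
    criterion: Optional[MODSCriterion] = None,
) -> tuple[list[PatientStay], dict[str, Optional[int]]]:
    """Generate ``cfg.n_patients`` stays plus a patient -> onset truth table."""
    cfg.validate()
    table = table or ScoreTable.default()
    criterion = criterion or MODSCriterion()
    rng = np.random.default_rng(cfg.seed)
    stays: list[PatientStay] = []
    truth: dict[str, Optional[int]] = {}
    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        stay = _simulate_stay(rng, cfg, pid, table, criterion)
        stays.append(stay)
        truth[pid] = stay.true_onset_hour
    return stays, truth


# ---------------------------------------------------------------------------
# Plain-text persistence (long-format CSV)
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return format(v, ".17g")


def write_observations(cohort: Iterable[PatientStay], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(OBS_HEADER)
        for stay in cohort:
            for o in stay.sorted_observations():
                w.writerow(
                    [
                        stay.patient_id,
                        _fmt(stay.age),
                        int(stay.first_icu_stay),
                        _fmt(o.time_offset),
                        o.variable,
                        _fmt(o.value),
                    ]
                )


def read_observations(path) -> list[PatientStay]:
    stays: dict[str, PatientStay] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != OBS_HEADER:
            raise ParseError(f"line 1: expected header {','.join(OBS_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(OBS_HEADER):
                raise ParseError(f"line {lineno}: expected {len(OBS_HEADER)} fields, got {len(row)}")
            pid, age_s, first_s, t_s, variable, value_s = row
            if variable not in VARIABLES:
                raise ParseError(f"line {lineno}: unknown variable {variable!r}")
            try:
                age = float(age_s)
                first = bool(int(first_s))
                t = float(t_s)
                value = float(value_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            if pid not in stays:
                stays[pid] = PatientStay(pid, age, first, [])
            stays[pid].observations.append(Observation(t, variable, value))
    for stay in stays.values():
        stay.observations.sort(key=lambda o: (o.time_offset, o.variable))
    return list(stays.values())


def write_truth(truth: Mapping[str, Optional[int]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "onset_hour"])
        for pid in sorted(truth):
            onset = truth[pid]
            w.writerow([pid, "" if onset is None else int(onset)])


def read_truth(path) -> dict[str, Optional[int]]:
    truth: dict[str, Optional[int]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[:2] != ["patient_id", "onset_hour"]:
            raise ParseError("line 1: expected header patient_id,onset_hour")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            truth[row[0]] = None if row[1] == "" else int(row[1])
    return truth
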