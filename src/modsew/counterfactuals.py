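"""Diverse, rule-screened counterfactual recommendations.

Given an entry predicted positive, a seeded derivative-free search (random
restart subset perturbation with greedy reversion) looks for minimally
changed feature vectors the model predicts on the desired side of the
threshold.  Candidates are repaired for inter-feature consistency — organ
sub-scores are recomputed from their governing raw aggregates, rolling
sub-scores never drop below current ones, and min <= mean <= max holds per
variable — so recommendations are physiologically coherent by construction;
an explicit rule screen re-checks the same constraints post hoc.

Diversity across the returned set is the determinant of a similarity
kernel ``K_ij = 1 / (1 + proximity(cf_i, cf_j))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .features import (
    CURRENT_SCORE_FEATURE,
    FEATURE_NAMES,
    ROLLING_SCORE_FEATURE,
    VAR_TOKEN,
)
from .scoring import ORGAN_AGGREGATES, ORGANS, VARIABLES, ScoreTable, score_variable


class CFError(ValueError):
    pass


#: Feature holding each organ's governing raw aggregate(s).
ORGAN_AGGREGATE_FEATURES: Mapping[str, tuple[tuple[str, str], ...]] = {
    organ: tuple(
        (f"current{stat.capitalize()}{VAR_TOKEN[var]}", var)
        for stat, var in sources
    )
    for organ, sources in ORGAN_AGGREGATES.items()
}

#: Admissible intervals per feature (broad physiological bounds).
_VAR_RANGES: Mapping[str, tuple[float, float]] = {
    "heart_rate": (30.0, 220.0),
    "dopamine": (0.0, 30.0),
    "oxygenation_index": (40.0, 600.0),
    "gcs": (3.0, 15.0),
    "lactate": (0.2, 20.0),
    "creatinine": (20.0, 900.0),
    "bilirubin": (1.0, 500.0),
    "platelets": (5.0, 700.0),
}


def default_feature_ranges() -> dict[str, tuple[float, float]]:
    ranges: dict[str, tuple[float, float]] = {"currentHour": (1.0, 10000.0)}
    for var in VARIABLES:
        for stat in ("Mean", "Max", "Min"):
            ranges[f"current{stat}{VAR_TOKEN[var]}"] = _VAR_RANGES[var]
    for organ in ORGANS:
        ranges[CURRENT_SCORE_FEATURE[organ]] = (0.0, 4.0)
        ranges[ROLLING_SCORE_FEATURE[organ]] = (0.0, 4.0)
    return ranges


_INT_FEATURES = {"currentMeanGcs", "currentMaxGcs", "currentMinGcs"} | {
    CURRENT_SCORE_FEATURE[o] for o in ORGANS
} | {ROLLING_SCORE_FEATURE[o] for o in ORGANS}


@dataclass(frozen=True)
class CFQuery:
    instance: pd.Series
    desired_class: int = 0
    k: int = 3
    immutable_features: frozenset = frozenset({"currentHour"})
    feature_ranges: Optional[Mapping[str, tuple[float, float]]] = None
    lambda_proximity: float = 0.5
    lambda_diversity: float = 1.0
    seed: int = 0
    budget: int = 5000  # model evaluations

    def __post_init__(self) -> None:
        if self.k < 1:
            raise CFError("k must be >= 1")
        if self.lambda_proximity < 0 or self.lambda_diversity < 0:
            raise CFError("lambda weights must be non-negative")
        missing = set(FEATURE_NAMES) - set(self.instance.index)
        if missing:
            raise CFError(f"instance missing features: {sorted(missing)}")

    def resolved_ranges(self) -> dict[str, tuple[float, float]]:
        ranges = default_feature_ranges()
        if self.feature_ranges:
            ranges.update(self.feature_ranges)
        return ranges


@dataclass(frozen=True)
class Rule:
    name: str
    predicate: Callable[[Mapping[str, float]], bool]

    def holds(self, features: Mapping[str, float]) -> bool:
        return bool(self.predicate(features))


RuleSet = Sequence[Rule]


def default_rules(table: Optional[ScoreTable] = None) -> list[Rule]:
    """Built-in consistency rules over a complete feature vector.

    (a) each current sub-score equals the score of its governing aggregate;
    (b) each rolling sub-score is >= the current one;
    (c) min <= mean <= max per variable.
    """
    table = table or ScoreTable.default()
    rules: list[Rule] = []

    def score_rule(organ: str) -> Rule:
        feats = ORGAN_AGGREGATE_FEATURES[organ]
        target = CURRENT_SCORE_FEATURE[organ]

        def pred(fv: Mapping[str, float], feats=feats, target=target) -> bool:
            derived = max(score_variable(fv[f], var, table) for f, var in feats)
            return abs(fv[target] - derived) < 1e-9

        return Rule(f"score_consistency_{organ}", pred)

    def rolling_rule(organ: str) -> Rule:
        cur, roll = CURRENT_SCORE_FEATURE[organ], ROLLING_SCORE_FEATURE[organ]
        return Rule(
            f"rolling_ge_current_{organ}",
            lambda fv, cur=cur, roll=roll: fv[roll] >= fv[cur] - 1e-9,
        )

    def order_rule(var: str) -> Rule:
        lo = f"currentMin{VAR_TOKEN[var]}"
        mid = f"currentMean{VAR_TOKEN[var]}"
        hi = f"currentMax{VAR_TOKEN[var]}"
        return Rule(
            f"min_mean_max_{var}",
            lambda fv, lo=lo, mid=mid, hi=hi: fv[lo] - 1e-9 <= fv[mid] <= fv[hi] + 1e-9,
        )

    for organ in ORGANS:
        rules.append(score_rule(organ))
        rules.append(rolling_rule(organ))
    for var in VARIABLES:
        rules.append(order_rule(var))
    return rules


def rule_screen(
    candidates: Iterable[pd.Series],
    rules: Optional[RuleSet] = None,
    table: Optional[ScoreTable] = None,
) -> list[pd.Series]:
    """Drop candidates violating any rule."""
    rules = list(rules) if rules is not None else default_rules(table)
    kept = []
    for cand in candidates:
        fv = cand.to_dict()
        if all(rule.holds(fv) for rule in rules):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def mad_scales(X: pd.DataFrame) -> pd.Series:
    """Per-feature median absolute deviation; zero-MAD features use 1."""
    med = X.median()
    mad = (X - med).abs().median()
    return mad.where(mad > 0, 1.0)


def proximity(
    x: pd.Series,
    cf: pd.Series,
    scales: pd.Series,
    mutable_features: Optional[Sequence[str]] = None,
) -> float:
    """Sum of scale-normalized absolute changes over mutable features."""
    feats = list(mutable_features) if mutable_features is not None else list(x.index)
    missing = [f for f in feats if f not in cf.index or f not in x.index]
    if missing:
        raise CFError(f"feature mismatch: {missing}")
    total = 0.0
    for f in feats:
        total += abs(float(x[f]) - float(cf[f])) / float(scales.get(f, 1.0))
    return total


def diversity(
    candidates: Sequence[pd.Series],
    scales: pd.Series,
    mutable_features: Optional[Sequence[str]] = None,
) -> float:
    """Determinant of the pairwise similarity kernel, in [0, 1]."""
    n = len(candidates)
    if n == 0:
        raise CFError("at least one candidate required")
    K = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = proximity(candidates[i], candidates[j], scales, mutable_features)
            K[i, j] = K[j, i] = 1.0 / (1.0 + d)
    return float(np.linalg.det(K))


# ---------------------------------------------------------------------------
# Repair and search
# ---------------------------------------------------------------------------

def repair(
    features: pd.Series,
    table: Optional[ScoreTable] = None,
    immutable: frozenset = frozenset({"currentHour"}),
) -> pd.Series:
    """Co-mutate derived features so the built-in rules hold.

    Orders min/mean/max, recomputes current sub-scores from their governing
    aggregates, and lifts rolling sub-scores to at least the current ones.
    """
    table = table or ScoreTable.default()
    fv = features.copy()
    for var in VARIABLES:
        lo_f, mid_f, hi_f = (
            f"currentMin{VAR_TOKEN[var]}",
            f"currentMean{VAR_TOKEN[var]}",
            f"currentMax{VAR_TOKEN[var]}",
        )
        lo, mid, hi = float(fv[lo_f]), float(fv[mid_f]), float(fv[hi_f])
        lo2, hi2 = min(lo, hi), max(lo, hi)
        fv[lo_f], fv[hi_f] = lo2, hi2
        fv[mid_f] = min(max(mid, lo2), hi2)
    for organ in ORGANS:
        target = CURRENT_SCORE_FEATURE[organ]
        derived = max(
            score_variable(float(fv[f]), var, table)
            for f, var in ORGAN_AGGREGATE_FEATURES[organ]
        )
        if target not in immutable:
            fv[target] = float(derived)
        roll = ROLLING_SCORE_FEATURE[organ]
        if roll not in immutable:
            fv[roll] = float(max(fv[roll], fv[target]))
    for f in _INT_FEATURES:
        if f in fv.index and f not in immutable:
            fv[f] = float(round(float(fv[f])))
    return fv


def _healthy_targets(x: pd.Series) -> dict[str, float]:
    """Per-feature healthy direction used to bias proposals."""
    from .scoring import HEALTHY_REFERENCE

    targets: dict[str, float] = {}
    for var in VARIABLES:
        for stat in ("Mean", "Max", "Min"):
            targets[f"current{stat}{VAR_TOKEN[var]}"] = HEALTHY_REFERENCE[var]
    for organ in ORGANS:
        targets[CURRENT_SCORE_FEATURE[organ]] = 0.0
        targets[ROLLING_SCORE_FEATURE[organ]] = 0.0
    return targets


@dataclass(frozen=True)
class CFCandidate:
    features: pd.Series
    probability: float
    proximity: float
    changed_features: tuple[str, ...]


@dataclass
class CounterfactualSet:
    candidates: list[CFCandidate]
    diversity_score: float
    act_before_hour: float
    diagnostics: str = ""

    def __len__(self) -> int:
        return len(self.candidates)


def _is_valid(prob: float, desired_class: int, threshold: float) -> bool:
    return prob < threshold if desired_class == 0 else prob >= threshold


def generate(
    model_fn: Callable[[np.ndarray], np.ndarray],
    query: CFQuery,
    threshold: float = 0.5,
    table: Optional[ScoreTable] = None,
    scales: Optional[pd.Series] = None,
    horizon: int = 12,
) -> CounterfactualSet:
    """Search for up to ``k`` valid, diverse counterfactuals.

    Returns an empty set with a diagnostic (never raises) when no valid
    candidate is found within the evaluation budget.
    """
    table = table or ScoreTable.default()
    x = query.instance[list(FEATURE_NAMES)].astype(float)
    if scales is None:
        scales = pd.Series(1.0, index=list(FEATURE_NAMES))
    rng = np.random.default_rng(query.seed)
    ranges = query.resolved_ranges()
    mutable = [f for f in FEATURE_NAMES if f not in query.immutable_features]
    if not mutable:
        raise CFError("no mutable features")

    p0 = float(model_fn(x.to_numpy(dtype=float)[None, :])[0])
    if _is_valid(p0, query.desired_class, threshold):
        raise CFError("instance already on the desired side of the threshold")

    evals = 1
    # pool keyed by changed-feature set: keep the closest candidate per key
    pool: dict[frozenset, CFCandidate] = {}

    def changed(fv: pd.Series) -> list[str]:
        return [f for f in mutable if abs(float(fv[f]) - float(x[f])) > 1e-12]

    def register(fv: pd.Series, prob: float) -> None:
        ch = changed(fv)
        if not ch:
            return
        key = frozenset(ch)
        prox = proximity(x, fv, scales, mutable)
        cand = CFCandidate(fv, prob, prox, tuple(sorted(ch)))
        if key not in pool or prox < pool[key].proximity:
            pool[key] = cand

    healthy = _healthy_targets(x)
    max_subset = min(10, len(mutable))
    batch_size = 32

    def evaluate(frames: list[pd.Series]) -> np.ndarray:
        nonlocal evals
        evals += len(frames)
        return np.asarray(model_fn(np.stack([f.to_numpy(dtype=float) for f in frames])))

    def propose(full_healthy: bool = False) -> pd.Series:
        cand = x.copy()
        if full_healthy:
            subset = mutable
        elif rng.random() < 0.25:
            # wide move: most mutable features at once (hard instances)
            size = int(rng.integers(max(len(mutable) // 2, 1), len(mutable) + 1))
            subset = list(rng.choice(mutable, size=size, replace=False))
        else:
            size = int(rng.integers(1, max_subset + 1))
            subset = list(rng.choice(mutable, size=size, replace=False))
        toward_healthy = full_healthy or rng.random() < 0.7
        for f in subset:
            lo, hi = ranges.get(f, (float(x[f]) - 1.0, float(x[f]) + 1.0))
            if full_healthy and f in healthy:
                cand[f] = healthy[f]
            elif toward_healthy and f in healthy:
                cand[f] = float(rng.uniform(*sorted((healthy[f], float(x[f])))))
            else:
                cand[f] = float(rng.uniform(lo, hi))
        return repair(cand, table, query.immutable_features)

    first_batch = True
    while evals < query.budget:
        proposals: list[pd.Series] = []
        for j in range(min(batch_size, query.budget - evals)):
            proposals.append(propose(full_healthy=first_batch and j == 0))
        first_batch = False
        if not proposals:
            break
        probs = evaluate(proposals)
        for cand, prob in zip(proposals, probs):
            if not _is_valid(float(prob), query.desired_class, threshold):
                continue
            # greedy reversion: restore features toward x while staying valid
            while evals < query.budget:
                ch = changed(cand)
                if len(ch) <= 1:
                    break
                trials = []
                for f in ch:
                    t = cand.copy()
                    t[f] = float(x[f])
                    trials.append(repair(t, table, query.immutable_features))
                t_probs = evaluate(trials)
                valid = [
                    (proximity(x, t, scales, mutable), t, float(p))
                    for t, p in zip(trials, t_probs)
                    if _is_valid(float(p), query.desired_class, threshold)
                ]
                if not valid:
                    break
                _, cand, prob = min(valid, key=lambda v: v[0])
            register(cand, float(prob))
        if len(pool) >= max(4 * query.k, 12):
            break

    act_before = float(x["currentHour"]) + horizon
    if not pool:
        return CounterfactualSet([], 0.0, act_before, diagnostics="no valid candidate within budget")

    ranked = sorted(pool.values(), key=lambda c: c.proximity)
    if query.lambda_diversity <= 0 or query.k == 1:
        chosen = ranked[: query.k]
    else:
        chosen = [ranked[0]]
        remaining = ranked[1:]
        while len(chosen) < query.k and remaining:
            best, best_score = None, -np.inf
            for cand in remaining:
                trial = [c.features for c in chosen] + [cand.features]
                div = diversity(trial, scales, mutable)
                score = query.lambda_diversity * np.log(max(div, 1e-300)) - query.lambda_proximity * cand.proximity
                if score > best_score:
                    best_score, best = score, cand
            chosen.append(best)
            remaining.remove(best)
    div = diversity([c.features for c in chosen], scales, mutable) if chosen else 0.0
    return CounterfactualSet(chosen, div, act_before)


def report_frame(cfset: CounterfactualSet, instance: pd.Series) -> pd.DataFrame:
    """Long-format change report: one row per (candidate, changed feature)."""
    rows = []
    for i, cand in enumerate(cfset.candidates):
        for f in cand.changed_features:
            rows.append(
                {
                    "candidate": i,
                    "feature": f,
                    "old": float(instance[f]),
                    "new": float(cand.features[f]),
                    "probability": cand.probability,
                    "proximity": cand.proximity,
                }
            )
    return pd.DataFrame(rows, columns=["candidate", "feature", "old", "new", "probability", "proximity"])
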