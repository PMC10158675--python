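"""Stacked-ensemble topologies and the Q-learning composition search.

Two built-in topologies: a two-layer stack (eight base slots feeding one
meta slot) and a three-layer stack (four first-layer bases pairwise feeding
two mid metas, which join two second-layer bases at the terminal meta).
Every slot is assigned one of the nine catalog algorithms by a tabular
Q-learning search whose state is the slot index, whose actions are the
catalog entries, and whose terminal reward is a validation metric of the
assembled ensemble; rewards are memoized per assignment so the number of
model fits stays bounded by the number of distinct assignments visited.

Meta learners are trained on out-of-fold base probability columns to avoid
stacking leakage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .learners import (
    CATALOG,
    LearnerHandle,
    LearnerSpec,
    class_weights,
    fit as fit_learner,
    oof_predictions,
)
from .metrics import auc as _auc


class EnsembleError(ValueError):
    pass


FEATURES = "features"


@dataclass(frozen=True)
class Slot:
    slot_id: str
    layer: int
    inputs: tuple[str, ...]  # (FEATURES,) for base slots, slot ids for metas


@dataclass(frozen=True)
class Topology:
    name: str
    slots: tuple[Slot, ...]

    def __post_init__(self) -> None:
        ids = [s.slot_id for s in self.slots]
        if len(set(ids)) != len(ids):
            raise EnsembleError("duplicate slot ids")
        known = set(ids)
        used_as_input: set[str] = set()
        for slot in self.slots:
            for inp in slot.inputs:
                if inp == FEATURES:
                    continue
                if inp not in known:
                    raise EnsembleError(f"slot {slot.slot_id} input {inp!r} undefined")
                producer = next(s for s in self.slots if s.slot_id == inp)
                if producer.layer >= slot.layer:
                    raise EnsembleError("inputs must come from earlier layers (acyclic)")
                used_as_input.add(inp)
        terminals = [s.slot_id for s in self.slots if s.slot_id not in used_as_input]
        if len(terminals) != 1:
            raise EnsembleError(f"expected exactly one terminal slot, got {terminals}")

    @property
    def base_slots(self) -> tuple[Slot, ...]:
        return tuple(s for s in self.slots if s.inputs == (FEATURES,))

    @property
    def meta_slots(self) -> tuple[Slot, ...]:
        return tuple(
            sorted(
                (s for s in self.slots if s.inputs != (FEATURES,)),
                key=lambda s: s.layer,
            )
        )

    @property
    def terminal(self) -> Slot:
        used = {inp for s in self.slots for inp in s.inputs if inp != FEATURES}
        return next(s for s in self.slots if s.slot_id not in used)

    @property
    def slot_ids(self) -> tuple[str, ...]:
        return tuple(s.slot_id for s in self.slots)


SUPERLEARNER = Topology(
    name="superlearner",
    slots=tuple(
        [Slot(f"base_{i}", 0, (FEATURES,)) for i in range(1, 9)]
        + [Slot("meta", 1, tuple(f"base_{i}" for i in range(1, 9)))]
    ),
)

SUBSUPERLEARNER = Topology(
    name="subsuperlearner",
    slots=(
        Slot("base1_1", 0, (FEATURES,)),
        Slot("base1_2", 0, (FEATURES,)),
        Slot("base1_3", 0, (FEATURES,)),
        Slot("base1_4", 0, (FEATURES,)),
        Slot("base2_1", 0, (FEATURES,)),
        Slot("base2_2", 0, (FEATURES,)),
        Slot("meta1_1", 1, ("base1_1", "base1_2")),
        Slot("meta1_2", 1, ("base1_3", "base1_4")),
        Slot("meta2", 2, ("meta1_1", "meta1_2", "base2_1", "base2_2")),
    ),
)

TOPOLOGIES: Mapping[str, Topology] = {
    SUPERLEARNER.name: SUPERLEARNER,
    SUBSUPERLEARNER.name: SUBSUPERLEARNER,
}


def config_space_size(topology, algorithms: Sequence[str] = CATALOG) -> int:
    """Number of distinct slot -> algorithm assignments.

    ``topology`` may be a :class:`Topology` or a bare slot count.
    """
    n_slots = topology if isinstance(topology, int) else len(topology.slots)
    if n_slots < 0:
        raise EnsembleError("slot count must be >= 0")
    return len(algorithms) ** n_slots


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

Assignment = dict  # slot_id -> algorithm id


def _check_assignment(topology: Topology, assignment: Mapping[str, str]) -> None:
    missing = set(topology.slot_ids) - set(assignment)
    if missing:
        raise EnsembleError(f"assignment missing slots: {sorted(missing)}")
    unknown = set(assignment.values()) - set(CATALOG)
    if unknown:
        raise EnsembleError(f"assignment uses unknown algorithms: {sorted(unknown)}")


def stack_forward(
    topology: Topology,
    assignment: Mapping[str, str],
    meta_models: Mapping[str, LearnerHandle],
    base_columns: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Propagate probability columns through the topology.

    ``base_columns`` maps algorithm id -> probability column for base slots
    (out-of-fold during training, model predictions at inference).
    """
    outputs: dict[str, np.ndarray] = {}
    for slot in topology.base_slots:
        algo = assignment[slot.slot_id]
        if algo not in base_columns:
            raise EnsembleError(f"missing cached column for algorithm {algo!r}")
        outputs[slot.slot_id] = np.asarray(base_columns[algo], dtype=float)
    for slot in topology.meta_slots:
        X_meta = np.column_stack([outputs[i] for i in slot.inputs])
        outputs[slot.slot_id] = meta_models[slot.slot_id].predict_proba(X_meta)
    return outputs


def fit_metas(
    topology: Topology,
    assignment: Mapping[str, str],
    base_columns: Mapping[str, np.ndarray],
    y: np.ndarray,
    seed: int = 0,
    weights=None,
    spec_overrides: Optional[Mapping[str, LearnerSpec]] = None,
) -> dict[str, LearnerHandle]:
    """Fit meta slots layer by layer on their input probability columns."""
    outputs: dict[str, np.ndarray] = {}
    for slot in topology.base_slots:
        algo = assignment[slot.slot_id]
        if algo not in base_columns:
            raise EnsembleError(f"missing cached column for algorithm {algo!r}")
        outputs[slot.slot_id] = np.asarray(base_columns[algo], dtype=float)
    metas: dict[str, LearnerHandle] = {}
    for slot in topology.meta_slots:
        X_meta = np.column_stack([outputs[i] for i in slot.inputs])
        algo = assignment[slot.slot_id]
        spec = (spec_overrides or {}).get(algo, LearnerSpec(algo, seed=seed))
        handle = fit_learner(spec, X_meta, y, weights=weights)
        metas[slot.slot_id] = handle
        outputs[slot.slot_id] = handle.predict_proba(X_meta)
    return metas


class EnsembleModel:
    """A fully assembled stacked ensemble ready for prediction."""

    def __init__(
        self,
        topology: Topology,
        assignment: Mapping[str, str],
        meta_models: Mapping[str, LearnerHandle],
        base_models: Optional[Mapping[str, LearnerHandle]] = None,
    ):
        _check_assignment(topology, assignment)
        self.topology = topology
        self.assignment = dict(assignment)
        self.meta_models = dict(meta_models)
        self.base_models = dict(base_models or {})

    def predict_proba(self, X) -> np.ndarray:
        needed = {self.assignment[s.slot_id] for s in self.topology.base_slots}
        missing = needed - set(self.base_models)
        if missing:
            raise EnsembleError(f"no fitted base models for: {sorted(missing)}")
        base_columns = {a: self.base_models[a].predict_proba(X) for a in needed}
        outputs = stack_forward(self.topology, self.assignment, self.meta_models, base_columns)
        return outputs[self.topology.terminal.slot_id]


def assemble(
    topology: Topology,
    assignment: Mapping[str, str],
    oof_columns: Mapping[str, np.ndarray],
    y,
    base_models: Optional[Mapping[str, LearnerHandle]] = None,
    seed: int = 0,
    weights=None,
    spec_overrides: Optional[Mapping[str, LearnerSpec]] = None,
) -> EnsembleModel:
    """Fit the meta layers on cached out-of-fold columns and return the model."""
    _check_assignment(topology, assignment)
    y = np.asarray(y).ravel()
    metas = fit_metas(topology, assignment, oof_columns, y, seed, weights, spec_overrides)
    return EnsembleModel(topology, assignment, metas, base_models)


# ---------------------------------------------------------------------------
# Q-learning composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QConfig:
    alpha: float = 0.1
    gamma: float = 0.85
    epsilon: float = 0.9
    episodes: int = 5000
    seed: int = 0
    epsilon_decay: bool = False  # optional linear decay to 0 over episodes
    reward_subsample: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise EnsembleError("alpha must be in (0, 1]")
        if not 0.0 <= self.gamma < 1.0:
            raise EnsembleError("gamma must be in [0, 1)")
        if not 0.0 <= self.epsilon <= 1.0:
            raise EnsembleError("epsilon must be in [0, 1]")
        if self.episodes < 1:
            raise EnsembleError("episodes must be >= 1")


@dataclass
class QTable:
    """Action values, rows = slots in topology order, columns = catalog."""

    slot_ids: tuple[str, ...]
    algorithms: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.slot_ids), len(self.algorithms)):
            raise EnsembleError("Q-table shape mismatch")

    @classmethod
    def zeros(cls, topology: Topology, algorithms: Sequence[str] = CATALOG) -> "QTable":
        return cls(
            slot_ids=topology.slot_ids,
            algorithms=tuple(algorithms),
            values=np.zeros((len(topology.slots), len(algorithms))),
        )

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["slot"] + list(self.algorithms))
            for sid, row in zip(self.slot_ids, self.values):
                w.writerow([sid] + [format(v, ".17g") for v in row])

    @classmethod
    def from_csv(cls, path) -> "QTable":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            rows = list(csv.reader(fh))
        algorithms = tuple(rows[0][1:])
        slot_ids = tuple(r[0] for r in rows[1:])
        values = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
        return cls(slot_ids, algorithms, values)


def readout(qtable: QTable) -> dict[str, str]:
    """Per-row argmax; ties resolve to the lowest catalog index."""
    if not np.all(np.isfinite(qtable.values)):
        raise EnsembleError("Q-table contains non-finite entries")
    return {
        sid: qtable.algorithms[int(np.argmax(row))]
        for sid, row in zip(qtable.slot_ids, qtable.values)
    }


class MemoizedReward:
    """Caches reward_fn per assignment; counts underlying evaluations."""

    def __init__(self, reward_fn: Callable[[Mapping[str, str]], float], slot_ids: Sequence[str]):
        self._fn = reward_fn
        self._slot_ids = tuple(slot_ids)
        self._cache: dict[tuple[str, ...], float] = {}
        self.calls = 0

    def __call__(self, assignment: Mapping[str, str]) -> float:
        key = tuple(assignment[s] for s in self._slot_ids)
        if key not in self._cache:
            self.calls += 1
            self._cache[key] = float(self._fn(dict(assignment)))
        return self._cache[key]


def qlearn_compose(
    topology: Topology,
    algorithms: Sequence[str],
    reward_fn: Callable[[Mapping[str, str]], float],
    qcfg: Optional[QConfig] = None,
) -> tuple[QTable, dict[str, str]]:
    """Search slot assignments by epsilon-greedy tabular Q-learning.

    Each episode fills the slots in order (state = slot index, so the
    learned table is exactly slots x algorithms) and receives a single
    terminal reward ``reward_fn(assignment)``.  Every visited cell is then
    updated toward its discounted return ``gamma^(n-1-s) * r``, and — since
    the environment's rewards are deterministic per assignment — only when
    the target improves the stored value, so ``Q[s, a]`` converges to the
    best discounted reward achievable having chosen ``a`` at slot ``s``
    and the per-row argmax readout coincides with exhaustive search once
    the optimum has been visited.  (A bootstrapped target
    ``r + gamma * max Q(s+1, .)`` cannot rank non-terminal slots here: with
    slot-index states it is independent of the slot's own action.)
    Rewards are memoized per assignment.
    """
    qcfg = qcfg or QConfig()
    algorithms = tuple(algorithms)
    if not algorithms:
        raise EnsembleError("empty algorithm list")
    rng = np.random.default_rng(qcfg.seed)
    qtable = QTable(
        slot_ids=topology.slot_ids,
        algorithms=algorithms,
        values=np.zeros((len(topology.slots), len(algorithms))),
    )
    memo = reward_fn if isinstance(reward_fn, MemoizedReward) else MemoizedReward(
        reward_fn, topology.slot_ids
    )
    q = qtable.values
    n_slots, n_actions = q.shape
    rewards_in_unit = True
    for episode in range(qcfg.episodes):
        eps = qcfg.epsilon
        if qcfg.epsilon_decay:
            eps = qcfg.epsilon * (1.0 - episode / qcfg.episodes)
        actions = np.empty(n_slots, dtype=int)
        for s in range(n_slots):
            if rng.random() < eps:
                actions[s] = rng.integers(n_actions)
            else:
                actions[s] = int(np.argmax(q[s]))
        assignment = {sid: algorithms[a] for sid, a in zip(topology.slot_ids, actions)}
        reward = memo(assignment)
        if not 0.0 <= reward <= 1.0:
            rewards_in_unit = False
        for s in range(n_slots):
            target = (qcfg.gamma ** (n_slots - 1 - s)) * reward
            if target > q[s, actions[s]]:
                q[s, actions[s]] += qcfg.alpha * (target - q[s, actions[s]])
        if rewards_in_unit:
            # terminal-only rewards in [0,1] with gamma < 1 keep Q in [0,1]
            assert np.all(q >= -1e-12) and np.all(q <= 1.0 + 1e-12)
    return qtable, readout(qtable)


# ---------------------------------------------------------------------------
# Reward construction for real compositions
# ---------------------------------------------------------------------------

class RewardEvaluator:
    """Validation-metric reward over assignments with per-algorithm caches.

    Out-of-fold train columns (meta features) and fitted full-train models
    with their validation columns are computed lazily, once per algorithm;
    assembling an assignment then only fits its meta slots.
    """

    def __init__(
        self,
        topology: Topology,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        metric: str = "auc",
        seed: int = 0,
        oof_k: int = 5,
        groups_train: Optional[np.ndarray] = None,
        spec_overrides: Optional[Mapping[str, LearnerSpec]] = None,
        use_class_weights: bool = True,
        subsample: Optional[int] = None,
        metric_fn: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
    ):
        self.topology = topology
        rng = np.random.default_rng(seed)
        X_train = np.asarray(X_train, dtype=float)
        y_train = np.asarray(y_train).ravel()
        if subsample is not None and subsample < len(y_train):
            idx = rng.choice(len(y_train), size=subsample, replace=False)
            X_train, y_train = X_train[idx], y_train[idx]
            groups_train = None if groups_train is None else np.asarray(groups_train)[idx]
        self.X_train, self.y_train = X_train, y_train
        self.X_val = np.asarray(X_val, dtype=float)
        self.y_val = np.asarray(y_val).ravel()
        self.seed = seed
        self.oof_k = oof_k
        self.groups_train = groups_train
        self.spec_overrides = dict(spec_overrides or {})
        self.weights = class_weights(y_train) if use_class_weights else None
        if metric_fn is not None:
            self._metric = metric_fn
        elif metric == "auc":
            self._metric = lambda y, p: _auc(y, p)
        elif metric == "yi":
            from .metrics import binary_metrics

            self._metric = lambda y, p: binary_metrics(y, p)[3]
        else:
            raise EnsembleError(f"unknown reward metric {metric!r}")
        self._oof: dict[str, np.ndarray] = {}
        self._models: dict[str, LearnerHandle] = {}
        self._val_cols: dict[str, np.ndarray] = {}

    def _spec(self, algo: str) -> LearnerSpec:
        return self.spec_overrides.get(algo, LearnerSpec(algo, seed=self.seed))

    def base_artifacts(self, algo: str) -> tuple[np.ndarray, LearnerHandle, np.ndarray]:
        if algo not in self._oof:
            spec = self._spec(algo)
            self._oof[algo] = oof_predictions(
                spec,
                self.X_train,
                self.y_train,
                k=self.oof_k,
                seed=self.seed,
                groups=self.groups_train,
                weights=self.weights,
            )
            model = fit_learner(spec, self.X_train, self.y_train, weights=self.weights)
            self._models[algo] = model
            self._val_cols[algo] = model.predict_proba(self.X_val)
        return self._oof[algo], self._models[algo], self._val_cols[algo]

    def build(self, assignment: Mapping[str, str]) -> tuple[EnsembleModel, np.ndarray]:
        """Assemble and return (model, validation probability column)."""
        _check_assignment(self.topology, assignment)
        base_algos = {assignment[s.slot_id] for s in self.topology.base_slots}
        for algo in sorted(base_algos):
            self.base_artifacts(algo)
        model = assemble(
            self.topology,
            assignment,
            {a: self._oof[a] for a in base_algos},
            self.y_train,
            base_models={a: self._models[a] for a in base_algos},
            seed=self.seed,
            weights=self.weights,
            spec_overrides=self.spec_overrides,
        )
        val_probs = stack_forward(
            self.topology,
            assignment,
            model.meta_models,
            {a: self._val_cols[a] for a in base_algos},
        )[self.topology.terminal.slot_id]
        return model, val_probs

    def __call__(self, assignment: Mapping[str, str]) -> float:
        _, val_probs = self.build(assignment)
        return float(self._metric(self.y_val, val_probs))
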