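"""Model-agnostic Shapley attribution via kernel-weighted least squares.

Absent features are masked by marginal replacement from a frozen,
checksummed background sample; the efficiency constraint (base value plus
attributions equals the model output) is enforced exactly, so every
explanation satisfies local accuracy by construction.  A brute-force
exact-Shapley enumerator (feasible up to 12 features) serves as the
validation oracle for the sampled estimator.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Optional, Sequence

import numpy as np


class ExplainError(ValueError):
    pass


ModelFn = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ShapExplanation:
    """Base value, per-feature attributions and the explained output."""

    base_value: float
    attributions: np.ndarray
    model_output: float
    feature_names: Optional[tuple[str, ...]] = None

    def local_accuracy_gap(self) -> float:
        return abs(self.base_value + float(np.sum(self.attributions)) - self.model_output)


class BackgroundSet:
    """Immutable reference matrix used to mask absent features."""

    def __init__(self, data: np.ndarray, feature_names: Optional[Sequence[str]] = None):
        data = np.array(data, dtype=float, copy=True)
        if data.ndim != 2 or data.shape[0] == 0:
            raise ExplainError("background must be a non-empty 2-D matrix")
        data.setflags(write=False)
        self._data = data
        self.feature_names = None if feature_names is None else tuple(feature_names)
        self.checksum = hashlib.sha256(data.tobytes()).hexdigest()

    @property
    def data(self) -> np.ndarray:
        return self._data

    @property
    def n_features(self) -> int:
        return self._data.shape[1]

    @classmethod
    def sample(cls, X, n: int = 100, seed: int = 0, feature_names=None) -> "BackgroundSet":
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(seed)
        if len(X) > n:
            X = X[rng.choice(len(X), size=n, replace=False)]
        return cls(X, feature_names)


def kernel_weight(M: int, s: int) -> float:
    """Coalition weight ``(M-1) / (C(M,s) * s * (M-s))`` for ``0 < s < M``."""
    if not 0 < s < M:
        raise ExplainError(
            "boundary coalitions (s=0, s=M) are handled by equality constraints"
        )
    return (M - 1) / (math.comb(M, s) * s * (M - s))


def _coalition_value(model_fn: ModelFn, x: np.ndarray, background: np.ndarray, mask: np.ndarray) -> float:
    """Mean model output with present features from x, absent from background."""
    composite = background.copy()
    composite[:, mask] = x[mask]
    return float(np.mean(model_fn(composite)))


def exact_shapley(
    model_fn: ModelFn,
    x,
    background: BackgroundSet,
    feature_names: Optional[Sequence[str]] = None,
) -> ShapExplanation:
    """Exact Shapley values by full 2^M enumeration (M <= 12)."""
    x = np.asarray(x, dtype=float).ravel()
    M = len(x)
    if M > 12:
        raise ExplainError("exact enumeration limited to M <= 12; use explain()")
    if background.n_features != M:
        raise ExplainError("background feature count mismatch")
    bg = background.data

    values: dict[int, float] = {}
    for bits in range(2**M):
        mask = np.array([(bits >> i) & 1 for i in range(M)], dtype=bool)
        values[bits] = _coalition_value(model_fn, x, bg, mask)

    base = values[0]
    fx = values[2**M - 1]
    phi = np.zeros(M)
    fact = math.factorial
    for i in range(M):
        for bits in range(2**M):
            if (bits >> i) & 1:
                continue
            s = bin(bits).count("1")
            weight = fact(s) * fact(M - s - 1) / fact(M)
            phi[i] += weight * (values[bits | (1 << i)] - values[bits])
    return ShapExplanation(
        base_value=base,
        attributions=phi,
        model_output=fx,
        feature_names=None if feature_names is None else tuple(feature_names),
    )


def _solve_constrained_wls(
    Z: np.ndarray, y: np.ndarray, w: np.ndarray, delta: float
) -> np.ndarray:
    """Weighted least squares with the efficiency constraint sum(phi)=delta.

    The last attribution is eliminated: ``phi_M = delta - sum(phi_others)``.
    """
    M = Z.shape[1]
    if M == 1:
        return np.array([delta])
    A = Z[:, :-1] - Z[:, -1:]
    target = y - Z[:, -1] * delta
    sw = np.sqrt(w)
    sol, *_ = np.linalg.lstsq(A * sw[:, None], target * sw, rcond=None)
    phi = np.empty(M)
    phi[:-1] = sol
    phi[-1] = delta - sol.sum()
    return phi


def explain(
    model_fn: ModelFn,
    x,
    background: BackgroundSet,
    n_coalitions: Optional[int] = None,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> ShapExplanation:
    """Kernel-weighted least-squares Shapley estimate.

    With ``n_coalitions`` omitted or at least ``2^M - 2`` all non-trivial
    coalitions are enumerated (exact); otherwise coalitions are sampled
    (seeded) from the kernel-weight size distribution, duplicates pooled.
    """
    x = np.asarray(x, dtype=float).ravel()
    M = len(x)
    if background.n_features != M:
        raise ExplainError("background feature count mismatch")
    bg = background.data
    full = 2**M - 2
    if n_coalitions is not None and n_coalitions < M + 2 and n_coalitions < full:
        raise ExplainError("n_coalitions must be at least M + 2")

    base = float(np.mean(model_fn(bg)))
    fx = float(np.mean(model_fn(x[None, :])))
    delta = fx - base

    if n_coalitions is None or n_coalitions >= full:
        masks, weights = [], []
        for s in range(1, M):
            w = kernel_weight(M, s)
            for combo in combinations(range(M), s):
                mask = np.zeros(M, dtype=bool)
                mask[list(combo)] = True
                masks.append(mask)
                weights.append(w)
    else:
        rng = np.random.default_rng(seed)
        sizes = np.arange(1, M)
        size_p = (M - 1) / (sizes * (M - sizes))
        size_p = size_p / size_p.sum()
        counts: dict[tuple[int, ...], int] = {}
        for _ in range(n_coalitions):
            s = int(rng.choice(sizes, p=size_p))
            combo = tuple(sorted(rng.choice(M, size=s, replace=False)))
            counts[combo] = counts.get(combo, 0) + 1
        masks, weights = [], []
        for combo, count in sorted(counts.items()):
            mask = np.zeros(M, dtype=bool)
            mask[list(combo)] = True
            masks.append(mask)
            # sampled coalitions carry multiplicity; size bias is already
            # in the sampling distribution, so weight by count alone
            weights.append(float(count))

    Z = np.array(masks, dtype=float)
    y = np.array([_coalition_value(model_fn, x, bg, m) for m in masks]) - base
    w = np.asarray(weights, dtype=float)
    phi = _solve_constrained_wls(Z, y, w, delta)
    return ShapExplanation(
        base_value=base,
        attributions=phi,
        model_output=fx,
        feature_names=None if feature_names is None else tuple(feature_names),
    )


def global_importance(
    explanations: Iterable[ShapExplanation],
) -> list[tuple[str, float]]:
    """Features ranked by mean absolute attribution, descending."""
    explanations = list(explanations)
    if not explanations:
        raise ExplainError("no explanations supplied")
    names = explanations[0].feature_names
    M = len(explanations[0].attributions)
    for e in explanations:
        if len(e.attributions) != M or e.feature_names != names:
            raise ExplainError("explanations have inconsistent feature sets")
    if names is None:
        names = tuple(f"f{i}" for i in range(M))
    mean_abs = np.mean([np.abs(e.attributions) for e in explanations], axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    return [(names[i], float(mean_abs[i])) for i in order]
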