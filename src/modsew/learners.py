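"""Nine-learner catalog behind a uniform fit / predict-probability contract.

Eight members are classical algorithms backed by scikit-learn; the ninth
(``dwnn``) is a deep-wide network implemented here in NumPy: a stack of
affine -> batch-norm -> ReLU blocks whose outputs are ALL concatenated
(optionally together with the raw input) and fed to a single sigmoid unit,
trained with class-weighted binary cross-entropy via Adam.

The two gradient-boosting slots are distinct catalog members; in this
offline build they are backed by scikit-learn's ``GradientBoostingClassifier``
and ``HistGradientBoostingClassifier`` respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier


class LearnerError(ValueError):
    pass


class NotFittedError(RuntimeError):
    pass


#: Catalog order is contractual: it defines the Q-table column order.
CATALOG: tuple[str, ...] = (
    "logistic_regression",
    "random_forest",
    "naive_bayes",
    "gradient_boosting_xgb",
    "gradient_boosting_lgbm",
    "knn",
    "decision_tree",
    "adaboost",
    "dwnn",
)


def catalog() -> list[str]:
    """The nine algorithm identifiers, in stable order."""
    return list(CATALOG)


def class_weights(labels: Sequence[int]) -> dict[int, float]:
    """Inverse-frequency class weights normalized to preserve total mass.

    ``w_c = n / (2 * n_c)`` so the weighted sample count equals ``n``.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise LearnerError("both classes required for class weights")
    n = len(y)
    return {int(c): n / (len(classes) * cnt) for c, cnt in zip(classes, counts)}


@dataclass(frozen=True)
class LearnerSpec:
    algorithm: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in CATALOG:
            raise LearnerError(f"unknown algorithm {self.algorithm!r}")


@dataclass(frozen=True)
class DWNNArch:
    block_widths: tuple[int, ...] = (64, 64, 64)
    batch_norm: bool = True
    concat_inputs: bool = True
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_widths) == 0:
            raise LearnerError("at least one block required")
        if any(w < 1 for w in self.block_widths):
            raise LearnerError("block widths must be positive")


# ---------------------------------------------------------------------------
# Deep-wide network (NumPy)
# ---------------------------------------------------------------------------

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class DWNNClassifier:
    """Skip-concatenate feed-forward binary classifier.

    Forward pass: ``h_0 = x``; each block computes
    ``a_l = relu(batchnorm(h_{l-1} W_l + b_l))``; the concatenation of all
    ``a_l`` (plus ``x`` when ``concat_inputs``) feeds one sigmoid output
    unit, so the loss reaches every block directly.
    """

    def __init__(self, arch: Optional[DWNNArch] = None, input_dim: Optional[int] = None):
        self.arch = arch or DWNNArch()
        self._params: Optional[dict] = None
        self._fitted = False
        if input_dim is not None:
            self._init_params(input_dim)

    # -- parameter setup ---------------------------------------------------

    def _init_params(self, input_dim: int) -> None:
        if input_dim < 1:
            raise LearnerError("input_dim must be >= 1")
        rng = np.random.default_rng(self.arch.seed)
        widths = list(self.arch.block_widths)
        blocks = []
        d_prev = input_dim
        for w in widths:
            blocks.append(
                {
                    "W": rng.normal(0.0, np.sqrt(2.0 / d_prev), size=(d_prev, w)),
                    "b": np.zeros(w),
                    "gamma": np.ones(w),
                    "beta": np.zeros(w),
                    "run_mean": np.zeros(w),
                    "run_var": np.ones(w),
                }
            )
            d_prev = w
        concat_dim = sum(widths) + (input_dim if self.arch.concat_inputs else 0)
        self._params = {
            "blocks": blocks,
            "w_out": rng.normal(0.0, np.sqrt(1.0 / concat_dim), size=concat_dim),
            "b_out": 0.0,
            "input_dim": input_dim,
            "concat_dim": concat_dim,
        }

    @property
    def concat_dim(self) -> int:
        if self._params is None:
            raise NotFittedError("network not initialized")
        return self._params["concat_dim"]

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool) -> tuple[np.ndarray, list[dict]]:
        p = self._params
        h = X
        caches = []
        acts = [X] if self.arch.concat_inputs else []
        for blk in p["blocks"]:
            z = h @ blk["W"] + blk["b"]
            if self.arch.batch_norm:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    blk["run_mean"] = _BN_MOMENTUM * blk["run_mean"] + (1 - _BN_MOMENTUM) * mu
                    blk["run_var"] = _BN_MOMENTUM * blk["run_var"] + (1 - _BN_MOMENTUM) * var
                else:
                    mu, var = blk["run_mean"], blk["run_var"]
                inv_std = 1.0 / np.sqrt(var + _BN_EPS)
                zhat = (z - mu) * inv_std
                u = blk["gamma"] * zhat + blk["beta"]
            else:
                zhat, inv_std, u = z, None, z
            a = np.maximum(u, 0.0)
            caches.append({"h_in": h, "z": z, "zhat": zhat, "inv_std": inv_std, "u": u, "a": a})
            acts.append(a)
            h = a
        c = np.concatenate(acts, axis=1)
        logit = c @ p["w_out"] + p["b_out"]
        return logit, caches + [{"concat": c}]

    @staticmethod
    def _sigmoid(x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out

    # -- training ----------------------------------------------------------

    def fit(self, X, y, sample_weight=None) -> "DWNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise LearnerError("X must be 2-D and aligned with y")
        if self._params is None or self._params["input_dim"] != X.shape[1]:
            self._init_params(X.shape[1])
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, dtype=float)

        arch = self.arch
        rng = np.random.default_rng(arch.seed + 1)
        p = self._params
        flat = self._flat_param_refs()
        m = [np.zeros_like(v) for v in (ref() for ref in flat["get"])]
        v_adam = [np.zeros_like(x) for x in m]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss, stall = np.inf, 0
        for _epoch in range(arch.epochs):
            order = rng.permutation(len(y))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(y), arch.batch_size):
                idx = order[start : start + arch.batch_size]
                if len(idx) < 2:
                    continue  # batch norm needs >= 2 rows
                grads, loss = self._backward(X[idx], y[idx], w[idx])
                epoch_loss += loss
                n_batches += 1
                step += 1
                for k, g in enumerate(grads):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * g * g
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v_adam[k] / (1 - beta2**step)
                    flat["set"][k](flat["get"][k]() - arch.learning_rate * mhat / (np.sqrt(vhat) + eps))
            mean_loss = epoch_loss / max(n_batches, 1)
            if mean_loss < best_loss - 1e-5:
                best_loss, stall = mean_loss, 0
            else:
                stall += 1
                if stall >= arch.patience:
                    break
        self._fitted = True
        return self

    def _flat_param_refs(self) -> dict:
        p = self._params
        getters, setters = [], []

        def add(container, key):
            getters.append(lambda c=container, k=key: c[k])

            def setter(val, c=container, k=key):
                c[k] = val

            setters.append(setter)

        for blk in p["blocks"]:
            for key in ("W", "b", "gamma", "beta"):
                add(blk, key)
        add(p, "w_out")
        add(p, "b_out")
        return {"get": getters, "set": setters}

    def _backward(self, X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[list, float]:
        p = self._params
        logit, caches = self._forward(X, training=True)
        c = caches[-1]["concat"]
        prob = self._sigmoid(logit)
        wsum = w.sum()
        eps = 1e-12
        loss = float(-(w * (y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))).sum() / wsum)

        dlogit = w * (prob - y) / wsum
        d_wout = c.T @ dlogit
        d_bout = float(dlogit.sum())
        dc = np.outer(dlogit, p["w_out"])

        widths = [blk["W"].shape[1] for blk in p["blocks"]]
        offset = p["input_dim"] if self.arch.concat_inputs else 0
        seg_grads = []
        for wdt in widths:
            seg_grads.append(dc[:, offset : offset + wdt])
            offset += wdt

        grads_blocks = [None] * len(p["blocks"])
        da_next = np.zeros_like(caches[len(p["blocks"]) - 1]["a"])
        for l in range(len(p["blocks"]) - 1, -1, -1):
            blk, cache = p["blocks"][l], caches[l]
            da = seg_grads[l] + da_next
            du = da * (cache["u"] > 0)
            if self.arch.batch_norm:
                zhat, inv_std = cache["zhat"], cache["inv_std"]
                n = len(X)
                dgamma = (du * zhat).sum(axis=0)
                dbeta = du.sum(axis=0)
                dzhat = du * blk["gamma"]
                dz = (inv_std / n) * (
                    n * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0)
                )
            else:
                dgamma = np.zeros_like(blk["gamma"])
                dbeta = np.zeros_like(blk["beta"])
                dz = du
            dW = cache["h_in"].T @ dz
            db = dz.sum(axis=0)
            grads_blocks[l] = (dW, db, dgamma, dbeta)
            da_next = dz @ blk["W"].T if l > 0 else None

        grads: list = []
        for g in grads_blocks:
            grads.extend(g)
        grads.append(d_wout)
        grads.append(d_bout)
        return grads, loss

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        if self._params is None:
            raise NotFittedError("call fit (or pass input_dim) first")
        X = np.asarray(X, dtype=float)
        logit, _ = self._forward(X, training=False)
        p1 = self._sigmoid(logit)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Uniform handles
# ---------------------------------------------------------------------------

class _ConstantModel:
    """Predicts a fixed class-1 probability (single-class fallback)."""

    def __init__(self, p1: float):
        self.p1 = float(np.clip(p1, 0.0, 1.0))
        self.classes_ = np.array([0, 1])

    def fit(self, X, y, sample_weight=None):
        return self

    def predict_proba(self, X):
        n = len(np.asarray(X))
        return np.column_stack([np.full(n, 1.0 - self.p1), np.full(n, self.p1)])


class LearnerHandle:
    """Fitted model exposing ``predict_proba(X) -> probability of class 1``."""

    def __init__(self, spec: LearnerSpec, estimator):
        self.spec = spec
        self._estimator = estimator
        self._fitted = False

    @property
    def fitted(self) -> bool:
        return self._fitted

    def fit(self, X, y, sample_weight=None) -> "LearnerHandle":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        if len(X) != len(y):
            raise LearnerError("X and y must have the same number of rows")
        if len(np.unique(y)) < 2:
            # degenerate fold (e.g. tiny grouped CV split): constant model
            self._estimator = _ConstantModel(float(np.mean(y)))
            self._estimator.fit(X, y)
            self._fitted = True
            return self
        if sample_weight is not None and self.spec.algorithm != "knn":
            self._estimator.fit(X, y, sample_weight=np.asarray(sample_weight, dtype=float))
        else:
            self._estimator.fit(X, y)
        self._fitted = True
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not self._fitted:
            raise NotFittedError(f"{self.spec.algorithm} not fitted")
        proba = self._estimator.predict_proba(np.asarray(X, dtype=float))
        if proba.ndim == 2:
            classes = list(getattr(self._estimator, "classes_", [0, 1]))
            if proba.shape[1] == 1 or 1 not in classes:
                # degenerate single-class fit: constant probability
                p = np.full(len(proba), float(classes[0] == 1))
            else:
                p = proba[:, classes.index(1)]
        else:
            p = np.asarray(proba)
        return np.clip(p, 0.0, 1.0)


def _make_estimator(spec: LearnerSpec):
    hp = dict(spec.hyperparameters)
    algo, seed = spec.algorithm, spec.seed
    if algo == "logistic_regression":
        return LogisticRegression(max_iter=1000, random_state=seed, **hp)
    if algo == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if algo == "naive_bayes":
        return GaussianNB(**hp)
    if algo == "gradient_boosting_xgb":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if algo == "gradient_boosting_lgbm":
        return HistGradientBoostingClassifier(random_state=seed, **hp)
    if algo == "knn":
        hp.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**hp)
    if algo == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if algo == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp)
    if algo == "dwnn":
        arch = hp.pop("arch", None) or DWNNArch(seed=seed, **hp)
        return DWNNClassifier(arch=arch)
    raise LearnerError(f"unknown algorithm {algo!r}")  # pragma: no cover


def fit(spec: LearnerSpec, X, y, weights=None) -> LearnerHandle:
    """Fit one catalog member; ``weights`` is a per-sample array or a
    per-class mapping (as returned by :func:`class_weights`)."""
    handle = LearnerHandle(spec, _make_estimator(spec))
    sw = _resolve_weights(weights, y)
    return handle.fit(X, y, sample_weight=sw)


def _resolve_weights(weights, y) -> Optional[np.ndarray]:
    if weights is None:
        return None
    if isinstance(weights, Mapping):
        y = np.asarray(y).ravel()
        return np.array([weights[int(v)] for v in y], dtype=float)
    return np.asarray(weights, dtype=float)


def build_dwnn(input_dim: int, arch: Optional[DWNNArch] = None) -> DWNNClassifier:
    """Instantiate (untrained) the skip-concatenate network."""
    return DWNNClassifier(arch=arch or DWNNArch(), input_dim=input_dim)


def oof_predictions(
    spec: LearnerSpec,
    X,
    y,
    k: int = 5,
    seed: int = 0,
    groups: Optional[Sequence] = None,
    weights=None,
) -> np.ndarray:
    """Out-of-fold probability column; folds are patient-grouped when
    ``groups`` is given, stratified otherwise."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if k < 2:
        raise LearnerError("k must be >= 2")
    if k > len(y):
        raise LearnerError("k exceeds the number of rows")
    sw = _resolve_weights(weights, y)
    oof = np.full(len(y), np.nan)
    if groups is not None:
        groups = np.asarray(groups)
        splitter = GroupKFold(n_splits=min(k, len(np.unique(groups))))
        split = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    for train_idx, test_idx in split:
        handle = LearnerHandle(spec, _make_estimator(spec))
        handle.fit(
            X[train_idx], y[train_idx], None if sw is None else sw[train_idx]
        )
        oof[test_idx] = handle.predict_proba(X[test_idx])
    if np.isnan(oof).any():
        raise LearnerError("out-of-fold predictions contain NaN (degenerate input?)")
    return oof


#: Small, documented hyperparameter grids (optional tuning; off by default).
DEFAULT_GRIDS: Mapping[str, Mapping[str, list]] = {
    "logistic_regression": {"C": [0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [50, 100], "max_depth": [None, 8]},
    "naive_bayes": {"var_smoothing": [1e-9, 1e-7]},
    "gradient_boosting_xgb": {"n_estimators": [50, 100], "max_depth": [2, 3]},
    "gradient_boosting_lgbm": {"max_iter": [50, 100]},
    "knn": {"n_neighbors": [5, 15]},
    "decision_tree": {"max_depth": [None, 8]},
    "adaboost": {"n_estimators": [50, 100]},
    "dwnn": {"learning_rate": [1e-3, 1e-2]},
}


def tune_learner(
    spec: LearnerSpec, X, y, k: int = 5, seed: int = 0, grid: Optional[Mapping] = None
) -> LearnerSpec:
    """Pick the grid point maximizing OOF AUC (five-fold)."""
    from itertools import product

    from .metrics import auc as _auc

    grid = dict(grid if grid is not None else DEFAULT_GRIDS[spec.algorithm])
    keys = sorted(grid)
    best_spec, best_score = spec, -np.inf
    for combo in product(*(grid[k_] for k_ in keys)):
        hp = dict(spec.hyperparameters)
        hp.update(dict(zip(keys, combo)))
        cand = LearnerSpec(spec.algorithm, hp, spec.seed)
        score = _auc(y, oof_predictions(cand, X, y, k=k, seed=seed))
        if score > best_score:
            best_score, best_spec = score, cand
    return best_spec
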