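"""Classifiers and cross-validation protocols.

Two model families score proteins for mitochondrial localization:

* an RBF-kernel SVM (scikit-learn solver) with grid-searched cost/gamma,
  emitting real-valued decision scores;
* a feed-forward network with maxout hidden units (5 linear pieces per
  unit), dropout 0.5 on hidden layers and a 2-way softmax output, trained by
  minibatch SGD with momentum rising linearly from 0.5 to 0.7, applied as a
  10-member ensemble whose prediction is the mean positive-class
  probability.  The network is a compact NumPy implementation; maxout pairs
  naturally with dropout because each unit's active linear piece can change
  under different dropout masks.

Cross-validation is stratified 10-fold.  The SVM protocol uses 9 folds for
training and 1 for testing per rotation; the network protocol uses 8 for
training, 1 for validation (epoch snapshot selection by validation AUC) and
1 for testing, each fold serving as validation or test exactly once.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .features import FeatureVector, layout_fingerprint

DEFAULT_COST_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 1e2, 1e3)
DEFAULT_GAMMA_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 1e2, 1e3, 1e4, 1e5)


class TrainingError(ValueError):
    """Degenerate or invalid training input."""


class CompatibilityError(ValueError):
    """Feature layout does not match the layout the model was trained on."""


@dataclass
class SVMConfig:
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    # default bandwidth adapts to feature dimension and variance; the fixed
    # grid above remains the search space for grid_search_svm
    cost: float = 10.0
    gamma: float | str = "scale"  # "scale" = 1/(d * Var[X])

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.cost_grid) or any(g <= 0 for g in self.gamma_grid):
            raise TrainingError("grid values must be positive")


@dataclass
class DNNConfig:
    hidden_sizes: tuple[int, ...] = (500, 500, 300)
    maxout_pieces: int = 5
    dropout: float = 0.5
    learning_rate: float = 0.01
    momentum_initial: float = 0.5
    momentum_final: float = 0.7
    max_epochs: int = 250
    batch_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_sizes:
            raise TrainingError("need at least one hidden layer")
        if not (0 <= self.dropout < 1):
            raise TrainingError("dropout must be in [0, 1)")
        if self.max_epochs < 1:
            raise TrainingError("epoch cap must be >= 1")


@dataclass
class TrainedModel:
    """A trained classifier plus the feature layout it expects.

    ``kind`` is "svm" (one member) or "dnn_ensemble" (10 members averaged).
    Prediction refuses feature vectors whose layout fingerprint differs from
    the one seen in training.
    """

    kind: str
    members: list
    fingerprint: str
    metadata: dict = field(default_factory=dict)


@dataclass
class CVResult:
    fold_scores: list[np.ndarray]
    fold_labels: list[np.ndarray]
    fold_aucs: list[float]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise TrainingError("non-finite feature values")
    if X.shape[0] != y.shape[0]:
        raise TrainingError("feature/label length mismatch")
    if len(np.unique(y)) < 2:
        raise TrainingError("training set contains a single class")
    return X, y


def stratified_kfold(labels: Sequence[int], k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Random stratified partition into k folds of near-equal class counts.

    Each record lands in exactly one fold; per-fold class counts differ by at
    most one from the exact quota.  Deterministic for a fixed seed.
    """
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise TrainingError(
                f"class {cls} has {len(idx)} records; cannot form {k} folds"
            )
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


# --- SVM --------------------------------------------------------------------

def train_svm(X: np.ndarray, y: np.ndarray, cost: float, gamma: float | str) -> SVC:
    """Fit an RBF-kernel SVM; decision scores increase with mitochondrial
    likeness.  No probability calibration — raw decision values feed the ROC
    and the specificity calibration directly."""
    X, y = _check_xy(X, y)
    # tight KKT tolerance keeps decision values reproducible to ~1e-6
    clf = SVC(C=cost, gamma=gamma, kernel="rbf", tol=1e-6)
    clf.fit(X, y)
    return clf


def _cv_auc_svm(X, y, cost, gamma, folds) -> float:
    aucs = []
    for i, test in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        clf = train_svm(X[train], y[train], cost, gamma)
        s = clf.decision_function(X[test])
        aucs.append(roc_auc_score(y[test], s))
    return float(np.mean(aucs))


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig | None = None,
    seed: int = 0,
    k: int = 10,
) -> tuple[float, float]:
    """Select (cost, gamma) maximizing mean stratified k-fold CV AUC.

    Ties break toward the smaller cost, then the smaller gamma, so the
    result is deterministic.
    """
    config = config or SVMConfig()
    X, y = _check_xy(X, y)
    folds = stratified_kfold(y, k=k, seed=seed)
    best, best_auc = None, -np.inf
    for cost in sorted(config.cost_grid):
        for gamma in sorted(config.gamma_grid):
            auc = _cv_auc_svm(X, y, cost, gamma, folds)
            if auc > best_auc:
                best, best_auc = (cost, gamma), auc
    return best


# --- maxout network ---------------------------------------------------------

class MaxoutNetwork:
    """Feed-forward net with maxout hidden activations and dropout.

    Hidden layer j computes ``max`` over ``pieces`` affine maps per unit;
    dropout (inverted scaling) is applied to the maxout outputs during
    training.  Output is a 2-unit softmax; loss is cross-entropy; optimizer
    is minibatch SGD with a linearly rising momentum schedule.
    """

    def __init__(self, n_in: int, config: DNNConfig, rng: np.random.Generator):
        self.config = config
        self.n_in = n_in
        p = config.maxout_pieces
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        prev = n_in
        for h in config.hidden_sizes:
            self.W.append(rng.normal(0.0, math.sqrt(2.0 / prev), size=(prev, h * p)))
            self.b.append(np.zeros(h * p))
            prev = h
        self.W.append(rng.normal(0.0, math.sqrt(2.0 / prev), size=(prev, 2)))
        self.b.append(np.zeros(2))
        self._vW = [np.zeros_like(w) for w in self.W]
        self._vb = [np.zeros_like(b) for b in self.b]

    def _forward(self, X: np.ndarray, train: bool, rng: np.random.Generator | None):
        p = self.config.maxout_pieces
        drop = self.config.dropout
        a = X
        cache = []
        for W, b, h in zip(self.W[:-1], self.b[:-1], self.config.hidden_sizes):
            z = (a @ W + b).reshape(len(a), h, p)
            arg = z.argmax(axis=2)
            out = np.take_along_axis(z, arg[:, :, None], axis=2)[:, :, 0]
            if train and drop > 0:
                mask = (rng.random(out.shape) >= drop) / (1.0 - drop)
            else:
                mask = np.ones_like(out)
            cache.append((a, arg, mask))
            a = out * mask
        logits = a @ self.W[-1] + self.b[-1]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, a, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Positive-class softmax probability per row (no dropout)."""
        probs, _, _ = self._forward(np.asarray(X, dtype=float), train=False, rng=None)
        return probs[:, 1]

    def _step(self, X, y, lr, momentum, rng):
        n = len(X)
        p = self.config.maxout_pieces
        probs, a_last, cache = self._forward(X, train=True, rng=rng)
        onehot = np.zeros((n, 2))
        onehot[np.arange(n), y] = 1.0
        dlogits = (probs - onehot) / n
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        grads_W[-1] = a_last.T @ dlogits
        grads_b[-1] = dlogits.sum(axis=0)
        da = dlogits @ self.W[-1].T
        for j in range(len(self.config.hidden_sizes) - 1, -1, -1):
            a_prev, arg, mask = cache[j]
            h = self.config.hidden_sizes[j]
            da = da * mask
            dz = np.zeros((n, h, p))
            np.put_along_axis(dz, arg[:, :, None], da[:, :, None], axis=2)
            dz = dz.reshape(n, h * p)
            grads_W[j] = a_prev.T @ dz
            grads_b[j] = dz.sum(axis=0)
            da = dz @ self.W[j].T
        for j in range(len(self.W)):
            self._vW[j] = momentum * self._vW[j] - lr * grads_W[j]
            self._vb[j] = momentum * self._vb[j] - lr * grads_b[j]
            self.W[j] += self._vW[j]
            self.b[j] += self._vb[j]

    def snapshot(self) -> list[np.ndarray]:
        return [w.copy() for w in self.W] + [b.copy() for b in self.b]

    def restore(self, snap: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [w.copy() for w in snap[:k]]
        self.b = [b.copy() for b in snap[k:]]


def train_dnn(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: DNNConfig,
) -> MaxoutNetwork:
    """Train one maxout network, keeping the epoch snapshot with the best
    validation AUC.

    Momentum rises linearly from its initial to its final value over the
    epoch cap.  If the cap is reached without perfect validation AUC the
    best snapshot is still returned, with ``cap_reached`` set in
    ``net.training_info`` — some feature sets simply cannot be fit within
    the budget.  Fully deterministic for a fixed config seed.
    """
    X_train, y_train = _check_xy(X_train, y_train)
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=int)
    if len(np.unique(y_val)) < 2:
        raise TrainingError("validation set needs both classes")
    rng = np.random.default_rng(config.seed)
    net = MaxoutNetwork(X_train.shape[1], config, rng)
    best_auc, best_snap, best_epoch = -np.inf, net.snapshot(), 0
    n = len(X_train)
    for epoch in range(config.max_epochs):
        t = epoch / max(1, config.max_epochs - 1)
        momentum = config.momentum_initial + t * (config.momentum_final - config.momentum_initial)
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            net._step(X_train[idx], y_train[idx], config.learning_rate, momentum, rng)
        val_auc = roc_auc_score(y_val, net.predict_proba(X_val))
        if val_auc > best_auc:
            best_auc, best_snap, best_epoch = val_auc, net.snapshot(), epoch + 1
    net.restore(best_snap)
    net.training_info = {
        "best_val_auc": float(best_auc),
        "best_epoch": best_epoch,
        "epochs_run": config.max_epochs,
        "cap_reached": best_auc < 1.0,
    }
    return net


def train_dnn_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    config: DNNConfig | None = None,
    seed: int = 0,
    fingerprint: str = "",
) -> TrainedModel:
    """Train k member networks by rotating the validation fold.

    Rotation i holds fold i out as validation and trains on the remaining
    k - 1 folds; the ensemble prediction is the mean of the members'
    positive-class probabilities.
    """
    config = config or DNNConfig()
    X, y = _check_xy(X, y)
    folds = stratified_kfold(y, k=k, seed=seed)
    seeds = np.random.SeedSequence(seed).generate_state(k) % (2**31)
    members = []
    for i, val in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        cfg = dataclasses.replace(config, seed=int(seeds[i]))
        members.append(train_dnn(X[train], y[train], X[val], y[val], cfg))
    return TrainedModel(
        kind="dnn_ensemble",
        members=members,
        fingerprint=fingerprint,
        metadata={"seed": seed, "k": k, "config": vars(config) | {}},
    )


def svm_model(X: np.ndarray, y: np.ndarray, config: SVMConfig | None = None,
              fingerprint: str = "") -> TrainedModel:
    config = config or SVMConfig()
    clf = train_svm(X, y, config.cost, config.gamma)
    return TrainedModel(kind="svm", members=[clf], fingerprint=fingerprint,
                        metadata={"cost": config.cost, "gamma": config.gamma})


def predict(model: TrainedModel, features: Sequence[FeatureVector] | np.ndarray,
            fingerprint: str | None = None) -> np.ndarray:
    """Score proteins with a trained model.

    Ensemble scores lie in [0, 1]; SVM scores are unbounded decision values.
    Both rank proteins for ROC analysis and specificity calibration.
    """
    if isinstance(features, np.ndarray):
        X = features
        fp = fingerprint
    else:
        if len(features) == 0:
            return np.array([])
        fps = {layout_fingerprint(v.layout) for v in features}
        if len(fps) > 1:
            raise CompatibilityError("mixed feature layouts")
        fp = fps.pop()
        X = np.vstack([v.values for v in features])
    if model.fingerprint and fp is not None and fp != model.fingerprint:
        raise CompatibilityError(
            f"feature layout {fp!r} differs from training layout {model.fingerprint!r}"
        )
    if X.size == 0:
        return np.array([])
    if model.kind == "svm":
        return model.members[0].decision_function(X)
    if model.kind == "dnn_ensemble":
        return np.mean([m.predict_proba(X) for m in model.members], axis=0)
    raise CompatibilityError(f"unknown model kind {model.kind!r}")


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    kind: str = "svm",
    svm_config: SVMConfig | None = None,
    dnn_config: DNNConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation under the protocol for ``kind``.

    svm: rotation i trains on k-1 folds and tests on fold i.
    dnn: rotation i tests on fold i, validates on fold (i+1) mod k and
    trains on the rest, so each fold is used as validation or test exactly
    once per role across the k rotations.
    """
    X, y = _check_xy(X, y)
    folds = stratified_kfold(y, k=k, seed=seed)
    seeds = np.random.SeedSequence(seed).generate_state(k) % (2**31)
    fold_scores, fold_labels, fold_aucs = [], [], []
    for i, test in enumerate(folds):
        if kind == "svm":
            cfg = svm_config or SVMConfig()
            train = np.concatenate([f for j, f in enumerate(folds) if j != i])
            clf = train_svm(X[train], y[train], cfg.cost, cfg.gamma)
            s = clf.decision_function(X[test])
        elif kind == "dnn":
            cfg = dataclasses.replace(dnn_config or DNNConfig(), seed=int(seeds[i]))
            val = folds[(i + 1) % k]
            train = np.concatenate(
                [f for j, f in enumerate(folds) if j != i and j != (i + 1) % k]
            )
            net = train_dnn(X[train], y[train], X[val], y[val], cfg)
            s = net.predict_proba(X[test])
        else:
            raise TrainingError(f"unknown model kind {kind!r}")
        fold_scores.append(s)
        fold_labels.append(y[test])
        fold_aucs.append(float(roc_auc_score(y[test], s)))
    return CVResult(fold_scores, fold_labels, fold_aucs)


# --- model bundle IO --------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model (weights, fingerprint, metadata) to one file."""
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise CompatibilityError(f"{path}: not a trained model bundle")
    return model
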