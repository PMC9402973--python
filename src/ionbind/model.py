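"""Feed-forward binary classifier and hyper-parameter grid search.

The network is defined by contract: ``hidden_layers`` ReLU layers of
``hidden_nodes`` units each, a sigmoid output unit, binary cross-entropy
loss, Adam optimizer, and early stopping on a held-out validation split.
It is realised on scikit-learn's multilayer perceptron, driven one epoch at
a time so that early stopping monitors validation *log-loss* (not accuracy,
which is uninformative at ~1.5% positive-class prevalence): training stops
once the validation loss has failed to improve for ``patience`` consecutive
epochs beyond the best epoch, whose weights are restored.

The grid search enumerates the three tuned hyper-parameters — number of
hidden layers (1..8), hidden nodes per layer (2..128 in powers of two) and
batch size (2..128 in powers of two) — scoring each configuration by
cross-validated MCC (or sensitivity) and breaking ties toward the simpler
network (fewer layers, fewer nodes, larger batch).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

TABLE_HIDDEN_LAYERS = (1, 2, 3, 4, 5, 6, 7, 8)
TABLE_HIDDEN_NODES = (2, 4, 8, 16, 32, 64, 128)
TABLE_BATCH_SIZES = (2, 4, 8, 16, 32, 64, 128)


class TrainingError(RuntimeError):
    pass


class DivergenceError(TrainingError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class NetConfig:
    """Architecture and training hyper-parameters of the classifier."""

    hidden_layers: int = 2
    hidden_nodes: int = 64
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4  # L2 penalty on the weights
    validation_fraction: float = 0.1
    positive_weight: float = 1.0  # optional minority-class weight (1 = off)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.hidden_nodes < 1 or self.batch_size < 1:
            raise ValueError(f"invalid network configuration: {self}")


class WindowNet(BaseEstimator, ClassifierMixin):
    """Feed-forward binary classifier over fragment feature vectors.

    Parameters mirror :class:`NetConfig`; ``threshold`` is the decision
    threshold applied to the predicted binding probability.  Deterministic
    given ``random_state``.
    """

    def __init__(
        self,
        hidden_layers: int = 2,
        hidden_nodes: int = 64,
        batch_size: int = 64,
        max_epochs: int = 200,
        patience: int = 10,
        learning_rate: float = 1e-3,
        weight_decay: float = 1e-4,
        validation_fraction: float = 0.1,
        threshold: float = 0.5,
        positive_weight: float = 1.0,
        random_state: int | None = 0,
    ):
        self.hidden_layers = hidden_layers
        self.hidden_nodes = hidden_nodes
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.positive_weight = positive_weight
        self.random_state = random_state

    def fit(self, X, y) -> "WindowNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        classes = np.unique(y)
        if classes.size < 2:
            raise TrainingError(
                "training labels contain a single class; both binding and "
                "non-binding fragments are required"
            )

        stratify = y if np.bincount(y, minlength=2).min() >= 2 else None
        if self.validation_fraction > 0:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X,
                y,
                test_size=self.validation_fraction,
                random_state=self.random_state,
                stratify=stratify,
            )
            if np.unique(y_tr).size < 2:  # tiny-data fallback
                X_tr, y_tr = X, y
                X_val, y_val = X, y
        else:
            X_tr, y_tr = X, y
            X_val, y_val = None, None

        # optional class weighting, realised as deterministic duplication of
        # the positive class in the training split (validation untouched)
        w = int(round(self.positive_weight))
        if w > 1:
            pos_idx = np.nonzero(y_tr == 1)[0]
            X_tr = np.vstack([X_tr] + [X_tr[pos_idx]] * (w - 1))
            y_tr = np.concatenate([y_tr] + [y_tr[pos_idx]] * (w - 1))

        mlp = MLPClassifier(
            hidden_layer_sizes=(self.hidden_nodes,) * self.hidden_layers,
            activation="relu",
            solver="adam",
            alpha=self.weight_decay,
            learning_rate_init=self.learning_rate,
            batch_size=min(self.batch_size, X_tr.shape[0]),
            shuffle=True,
            random_state=self.random_state,
            max_iter=1,
        )

        best_loss = np.inf
        best_weights = None
        best_epoch = -1
        history: list[float] = []
        val_history: list[float] = []
        import warnings as _warnings

        for epoch in range(self.max_epochs):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # per-epoch non-convergence
                mlp.partial_fit(X_tr, y_tr, classes=classes)
            train_loss = mlp.loss_
            if not np.isfinite(train_loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch} (config: "
                    f"layers={self.hidden_layers}, nodes={self.hidden_nodes}, "
                    f"batch={self.batch_size}, lr={self.learning_rate})"
                )
            history.append(float(train_loss))
            if X_val is None:
                continue
            val_loss = log_loss(y_val, mlp.predict_proba(X_val), labels=classes)
            val_history.append(float(val_loss))
            if val_loss < best_loss - 1e-12:
                best_loss = val_loss
                best_epoch = epoch
                best_weights = (
                    [w.copy() for w in mlp.coefs_],
                    [b.copy() for b in mlp.intercepts_],
                )
            elif epoch - best_epoch > self.patience:
                break

        if best_weights is not None:
            mlp.coefs_, mlp.intercepts_ = best_weights
        self.mlp_ = mlp
        self.classes_ = classes
        self.loss_curve_ = history
        self.validation_loss_curve_ = val_history
        self.best_epoch_ = best_epoch if best_weights is not None else len(history) - 1
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty((0, 2))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was trained with "
                f"{self.n_features_in_}"
            )
        return self.mlp_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        if proba.shape[0] == 0:
            return np.empty(0, dtype=int)
        return (proba[:, 1] > self.threshold).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "mlp_"):
            raise TrainingError("WindowNet must be fitted before prediction")


@dataclass
class TrainedModel:
    """A fitted classifier with its configuration and training history."""

    net: WindowNet
    config: NetConfig
    history: list = field(default_factory=list)

    @property
    def threshold(self) -> float:
        return self.net.threshold


def train(X, y, config: NetConfig = NetConfig()) -> TrainedModel:
    """Train a classifier with the given configuration (thin wrapper)."""
    net = WindowNet(
        hidden_layers=config.hidden_layers,
        hidden_nodes=config.hidden_nodes,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
        validation_fraction=config.validation_fraction,
        positive_weight=config.positive_weight,
        random_state=config.seed,
    )
    net.fit(X, y)
    return TrainedModel(net=net, config=config, history=list(net.loss_curve_))


def predict(model, X, threshold: float | None = None):
    """Binding probabilities and thresholded labels for a feature matrix."""
    proba = model.predict_proba(np.asarray(X, dtype=float))[:, 1] if np.size(X) else np.empty(0)
    thr = model.threshold if threshold is None else threshold
    return proba, (proba > thr).astype(int)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: TrainedModel, path) -> None:
    """Serialize config + weights to JSON (text container)."""
    net = model.net
    d = {
        "config": asdict(model.config),
        "threshold": net.threshold,
        "coefs": [w.tolist() for w in net.mlp_.coefs_],
        "intercepts": [b.tolist() for b in net.mlp_.intercepts_],
        "n_features_in": net.n_features_in_,
        "loss_curve": model.history,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh)


class LoadedModel:
    """Checkpoint-backed model: a plain numpy forward pass (ReLU + sigmoid)."""

    def __init__(self, coefs, intercepts, threshold: float, config: NetConfig):
        self.coefs = [np.asarray(w, dtype=float) for w in coefs]
        self.intercepts = [np.asarray(b, dtype=float) for b in intercepts]
        self.threshold = threshold
        self.config = config
        self.n_features_in_ = self.coefs[0].shape[0]

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty((0, 2))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, checkpoint expects {self.n_features_in_}"
            )
        a = X
        for w, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            a = np.maximum(a @ w + b, 0.0)
        z = (a @ self.coefs[-1] + self.intercepts[-1]).ravel()
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        if proba.shape[0] == 0:
            return np.empty(0, dtype=int)
        return (proba[:, 1] > self.threshold).astype(int)


def load_checkpoint(path) -> LoadedModel:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    try:
        config = NetConfig(**d["config"])
        return LoadedModel(d["coefs"], d["intercepts"], float(d["threshold"]), config)
    except (KeyError, TypeError) as exc:
        raise TrainingError(f"malformed checkpoint {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# hyper-parameter grid search


def full_grid(
    layers: Sequence[int] = TABLE_HIDDEN_LAYERS,
    nodes: Sequence[int] = TABLE_HIDDEN_NODES,
    batches: Sequence[int] = TABLE_BATCH_SIZES,
) -> list[NetConfig]:
    """The exhaustive 8 x 7 x 7 hyper-parameter grid."""
    return [
        NetConfig(hidden_layers=l, hidden_nodes=n, batch_size=b)
        for l, n, b in itertools.product(layers, nodes, batches)
    ]


def budgeted_grid(budget: int, seed: int = 0) -> list[NetConfig]:
    """A seeded random subset of the full grid (deterministic)."""
    grid = full_grid()
    if budget >= len(grid):
        return grid
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(grid), size=budget, replace=False))
    return [grid[i] for i in idx]


def grid_search(
    X,
    y,
    grid: Sequence[NetConfig] | None = None,
    folds: int = 5,
    criterion: str = "MCC",
    seed: int = 0,
    standardize: bool = True,
):
    """Cross-validated search over network configurations.

    Returns ``(best_config, results)`` where ``results`` is a DataFrame with
    one row per configuration carrying pooled Sn/Sp/Acc/MCC.  Ties on the
    criterion break toward fewer layers, fewer nodes, larger batch.
    """
    from .evaluation import compute_metrics, ConfusionCounts

    if grid is None:
        grid = full_grid()
    grid = list(grid)
    if len(grid) < 1:
        raise ValueError("hyper-parameter grid is empty")
    if criterion not in ("MCC", "Sn"):
        raise ValueError(f"criterion must be 'MCC' or 'Sn', got {criterion!r}")

    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    rows = []
    for cfg in grid:
        tp = fp = tn = fn = 0
        for k, (tr, te) in enumerate(splits):
            X_tr, X_te = X[tr], X[te]
            if standardize:
                scaler = StandardScaler().fit(X_tr)
                X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
            net = WindowNet(
                hidden_layers=cfg.hidden_layers,
                hidden_nodes=cfg.hidden_nodes,
                batch_size=cfg.batch_size,
                max_epochs=cfg.max_epochs,
                patience=cfg.patience,
                learning_rate=cfg.learning_rate,
                weight_decay=cfg.weight_decay,
                validation_fraction=cfg.validation_fraction,
                positive_weight=cfg.positive_weight,
                random_state=seed + k,
            ).fit(X_tr, y[tr])
            pred = net.predict(X_te)
            tp += int(((pred == 1) & (y[te] == 1)).sum())
            fp += int(((pred == 1) & (y[te] == 0)).sum())
            tn += int(((pred == 0) & (y[te] == 0)).sum())
            fn += int(((pred == 0) & (y[te] == 1)).sum())
        m = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        rows.append(
            {
                "hidden_layers": cfg.hidden_layers,
                "hidden_nodes": cfg.hidden_nodes,
                "batch_size": cfg.batch_size,
                "Sn": m.sn,
                "Sp": m.sp,
                "Acc": m.acc,
                "MCC": m.mcc,
            }
        )
    results = pd.DataFrame(rows)

    key = "MCC" if criterion == "MCC" else "Sn"
    scores = results[key].to_numpy(dtype=float)
    scores = np.where(np.isnan(scores), -np.inf, scores)
    order = sorted(
        range(len(grid)),
        key=lambda i: (
            -scores[i],
            grid[i].hidden_layers,
            grid[i].hidden_nodes,
            -grid[i].batch_size,
        ),
    )
    return grid[order[0]], results
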