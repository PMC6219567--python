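"""Feed-forward neural network for nuclear/cytosolic classification.

The classifier is a fully connected network — input layer, three hidden
layers with ReLU activations, softmax output over the two compartments —
trained by mini-batch stochastic gradient descent with backpropagation on
the cross-entropy loss. Overfitting control follows the usual recipe for
wide tabular inputs: inverted dropout on the input features and on every
hidden layer, plus L1 and L2 weight penalties. All hyperparameters the
procedure does not pin down (layer widths, learning rate, penalty
magnitudes, epochs, batch size) live in ModelConfig and are chosen by
random search minimizing validation misclassification.

Features are standardized to zero mean / unit variance using statistics
of the training split only; the standardization parameters, the feature
registry hash and the config are serialized with the weights, and a model
refuses to score a feature matrix whose registry hash differs.

Implemented directly on numpy: the network is small (~10^5 weights) and a
first-class implementation keeps training bit-reproducible given a seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .genomic import FeatureMatrix

__all__ = [
    "ModelConfig",
    "StandardizationParams",
    "TrainedModel",
    "standardize",
    "train",
    "random_search",
    "predict_proba",
    "classify",
    "permutation_importance",
    "save_model",
    "load_model",
]

CLASSES = ("cytosolic", "nuclear")  # output column order is (nuclear, cytosolic)
_POSITIVE = "nuclear"


@dataclass(frozen=True)
class ModelConfig:
    hidden_sizes: tuple[int, ...] = (128, 128, 64)
    hidden_dropout: float = 0.5
    input_dropout: float = 0.1
    l1: float = 1e-6
    l2: float = 1e-4
    learning_rate: float = 0.003
    momentum: float = 0.9
    epochs: int = 60
    batch_size: int = 64
    patience: int | None = 10  # early stopping on val misclassification
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))
        if any(h < 1 for h in self.hidden_sizes) or not self.hidden_sizes:
            raise ValidationError("hidden_sizes must be positive integers")
        for name in ("hidden_dropout", "input_dropout"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValidationError(f"{name} must be in [0, 1), got {rate}")
        if self.l1 < 0 or self.l2 < 0:
            raise ValidationError("l1/l2 penalties must be non-negative")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be positive")

    def n_parameters(self, n_features: int) -> int:
        dims = [n_features, *self.hidden_sizes, 2]
        return sum(dims[i] * dims[i + 1] + dims[i + 1] for i in range(len(dims) - 1))


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature mean/sd of the training split.

    Zero-variance features are centered only (divisor forced to 1) and
    flagged, so applying the transform never divides by zero.
    """

    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.sd


def standardize(X_train: np.ndarray) -> tuple[StandardizationParams, np.ndarray]:
    """Fit standardization on the training matrix; return params and the
    transformed training matrix."""
    X = np.asarray(X_train, dtype=np.float64)
    if X.size == 0:
        raise ValidationError("cannot standardize an empty matrix")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero_var = sd == 0.0
    sd = np.where(zero_var, 1.0, sd)
    params = StandardizationParams(mean=mean, sd=sd, zero_variance=zero_var)
    return params, params.transform(X)


def _encode_labels(y: Sequence[str] | np.ndarray) -> np.ndarray:
    arr = np.asarray(y)
    out = np.empty(arr.shape[0], dtype=np.int64)
    for i, lab in enumerate(arr):
        if lab not in CLASSES:
            raise ValidationError(f"unknown label {lab!r}; expected one of {CLASSES}")
        out[i] = CLASSES.index(lab)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(weights, X):
    """Inference pass (no dropout). Returns class probabilities."""
    a = X
    for W, b in weights[:-1]:
        a = np.maximum(a @ W + b, 0.0)
    W, b = weights[-1]
    return _softmax(a @ W + b)


@dataclass
class TrainedModel:
    weights: list[tuple[np.ndarray, np.ndarray]]
    standardization: StandardizationParams
    config: ModelConfig
    registry_hash: str | None
    history: list[dict] = field(default_factory=list)

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for W, b in self.weights:
            h.update(np.ascontiguousarray(W).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
        return h.hexdigest()

    @property
    def n_features(self) -> int:
        return self.weights[0][0].shape[0]


def _resolve_features(model: TrainedModel, X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        if model.registry_hash is not None and X.registry_hash != model.registry_hash:
            raise ValidationError(
                "feature registry hash mismatch: model was trained on a "
                "different column registry"
            )
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValidationError("feature matrix contains missing/non-finite values")
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    return X


def train(
    config: ModelConfig,
    X_train,
    y_train,
    X_val=None,
    y_val=None,
    registry_hash: str | None = None,
) -> TrainedModel:
    """Train the network with mini-batch SGD + momentum.

    X_train/X_val may be FeatureMatrix objects (registry hashes must then
    agree) or plain arrays. Labels are strings over {nuclear, cytosolic}.
    Dropout is active only here, never at inference. History records
    per-epoch train loss and, when a validation set is given, validation
    loss and misclassification. Training aborts on non-finite loss.
    """
    if isinstance(X_train, FeatureMatrix):
        if registry_hash is None:
            registry_hash = X_train.registry_hash
        elif registry_hash != X_train.registry_hash:
            raise ValidationError("registry_hash argument disagrees with training matrix")
        X_train = X_train.values
    if isinstance(X_val, FeatureMatrix):
        if registry_hash is not None and X_val.registry_hash != registry_hash:
            raise ValidationError("train/val feature registries differ")
        X_val = X_val.values
    X_train = np.asarray(X_train, dtype=np.float64)
    y = _encode_labels(y_train)
    if X_train.shape[0] != y.shape[0]:
        raise ValidationError("X_train and y_train length mismatch")

    params, Xs = standardize(X_train)
    has_val = X_val is not None
    if has_val:
        Xv = params.transform(np.asarray(X_val, dtype=np.float64))
        yv = _encode_labels(y_val)

    rng = np.random.default_rng(config.seed)
    dims = [Xs.shape[1], *config.hidden_sizes, 2]
    weights: list[tuple[np.ndarray, np.ndarray]] = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        weights.append((W, np.zeros(d_out)))
    velocity = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]

    n = Xs.shape[0]
    history: list[dict] = []
    best_miss = np.inf
    best_weights = None
    stall = 0
    eye2 = np.eye(2)

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = Xs[idx]
            yb = y[idx]
            m = xb.shape[0]

            # forward with inverted dropout
            if config.input_dropout > 0:
                mask = rng.random(xb.shape) >= config.input_dropout
                a = xb * mask / (1.0 - config.input_dropout)
            else:
                a = xb
            activations = [a]
            masks = []
            for W, b in weights[:-1]:
                a = np.maximum(a @ W + b, 0.0)
                if config.hidden_dropout > 0:
                    mask = rng.random(a.shape) >= config.hidden_dropout
                    a = a * mask / (1.0 - config.hidden_dropout)
                    masks.append(mask)
                else:
                    masks.append(None)
                activations.append(a)
            W_out, b_out = weights[-1]
            probs = _softmax(activations[-1] @ W_out + b_out)

            loss = -np.mean(np.log(probs[np.arange(m), yb] + 1e-12))
            loss += config.l1 * sum(np.abs(W).sum() for W, _ in weights)
            loss += 0.5 * config.l2 * sum((W**2).sum() for W, _ in weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: lr={config.learning_rate}, "
                    f"l1={config.l1}, l2={config.l2} — lower the learning rate"
                )
            epoch_loss += loss * m

            # backward
            delta = (probs - eye2[yb]) / m
            grads: list[tuple[np.ndarray, np.ndarray]] = []
            for layer in range(len(weights) - 1, -1, -1):
                W, b = weights[layer]
                a_prev = activations[layer]
                gW = a_prev.T @ delta + config.l1 * np.sign(W) + config.l2 * W
                gb = delta.sum(axis=0)
                grads.append((gW, gb))
                if layer > 0:
                    delta = delta @ W.T
                    a_here = activations[layer]
                    if masks[layer - 1] is not None:
                        delta = delta * masks[layer - 1] / (1.0 - config.hidden_dropout)
                    delta = delta * (a_here > 0)
            grads.reverse()
            for layer, ((gW, gb), (vW, vb), (W, b)) in enumerate(
                zip(grads, velocity, weights)
            ):
                vW = config.momentum * vW - config.learning_rate * gW
                vb = config.momentum * vb - config.learning_rate * gb
                velocity[layer] = (vW, vb)
                weights[layer] = (W + vW, b + vb)

        record = {"epoch": epoch, "train_loss": float(epoch_loss / n)}
        if has_val:
            pv = _forward(weights, Xv)
            val_loss = float(-np.mean(np.log(pv[np.arange(len(yv)), yv] + 1e-12)))
            miss = float(np.mean(pv.argmax(axis=1) != yv))
            record["val_loss"] = val_loss
            record["val_misclassification"] = miss
            if miss < best_miss - 1e-12:
                best_miss = miss
                best_weights = [(W.copy(), b.copy()) for W, b in weights]
                stall = 0
            else:
                stall += 1
        history.append(record)
        if config.patience is not None and has_val and stall > config.patience:
            break

    if config.patience is not None and best_weights is not None:
        weights = best_weights
    return TrainedModel(
        weights=weights,
        standardization=params,
        config=config,
        registry_hash=registry_hash,
        history=history,
    )


def predict_proba(model: TrainedModel, X) -> pd.DataFrame:
    """Class probabilities, columns (P_nuclear, P_cytosolic); dropout off."""
    index = X.data.index if isinstance(X, FeatureMatrix) else None
    Xs = model.standardization.transform(_resolve_features(model, X))
    probs = _forward(model.weights, Xs)
    return pd.DataFrame(
        {"P_nuclear": probs[:, CLASSES.index("nuclear")],
         "P_cytosolic": probs[:, CLASSES.index("cytosolic")]},
        index=index,
    )


def classify(proba: pd.DataFrame, cutoff: float = 0.5) -> pd.Series:
    """Hard labels from probabilities: nuclear iff P_nuclear > cutoff.

    A probability exactly at the cutoff goes to cytosolic.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValidationError(f"cutoff must be in [0, 1], got {cutoff}")
    labels = np.where(proba["P_nuclear"].to_numpy() > cutoff, "nuclear", "cytosolic")
    return pd.Series(labels, index=proba.index, name="label")


def random_search(
    space: Mapping[str, Sequence],
    budget: int,
    seed: int,
    X_train,
    y_train,
    X_val,
    y_val,
    base_config: ModelConfig | None = None,
) -> tuple[ModelConfig, list[dict]]:
    """Random hyperparameter search minimizing validation misclassification.

    `space` maps ModelConfig field names to candidate value lists. Ties are
    broken by smaller parameter count, then by earlier draw. Returns the
    winning config and the full trial log.
    """
    if budget < 1:
        raise ValidationError("budget must be >= 1")
    if not space:
        raise ValidationError("empty search space")
    base = base_config or ModelConfig()
    bad = set(space) - set(asdict(base))
    if bad:
        raise ValidationError(f"unknown config fields in search space: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    n_features = (
        X_train.values.shape[1]
        if isinstance(X_train, FeatureMatrix)
        else np.asarray(X_train).shape[1]
    )
    trials: list[dict] = []
    best: tuple[float, int, int] | None = None  # (miss, n_params, draw)
    best_config = None
    for draw in range(budget):
        sampled = {
            name: values[int(rng.integers(len(values)))] for name, values in space.items()
        }
        config = replace(base, **sampled, seed=int(rng.integers(2**31 - 1)))
        try:
            model = train(config, X_train, y_train, X_val, y_val)
            miss = model.history[-1]["val_misclassification"]
            if config.patience is not None:
                miss = min(h["val_misclassification"] for h in model.history)
            error = None
        except RuntimeError as exc:  # divergent trial (e.g. lr too high)
            miss = float("inf")
            error = str(exc)
        trials.append(
            {
                "draw": draw,
                "config": {**sampled, "seed": config.seed},
                "val_misclassification": miss,
                "error": error,
            }
        )
        key = (miss, config.n_parameters(n_features), draw)
        if best is None or key < best:
            best = key
            best_config = config
    assert best_config is not None
    return best_config, trials


def permutation_importance(
    model: TrainedModel, X, y, seed: int = 0, n_repeats: int = 1
) -> np.ndarray:
    """Accuracy drop when each feature column is shuffled (mean over repeats)."""
    Xa = _resolve_features(model, X)
    y_idx = _encode_labels(y)
    rng = np.random.default_rng(seed)
    base_acc = np.mean(
        _forward(model.weights, model.standardization.transform(Xa)).argmax(axis=1)
        == y_idx
    )
    drops = np.zeros(Xa.shape[1])
    for j in range(Xa.shape[1]):
        for _ in range(n_repeats):
            Xp = Xa.copy()
            Xp[:, j] = Xp[rng.permutation(Xa.shape[0]), j]
            acc = np.mean(
                _forward(
                    model.weights, model.standardization.transform(Xp)
                ).argmax(axis=1)
                == y_idx
            )
            drops[j] += (base_acc - acc) / n_repeats
    return drops


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize weights, standardization, config and registry hash."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, (W, b) in enumerate(model.weights):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    arrays["mean"] = model.standardization.mean
    arrays["sd"] = model.standardization.sd
    arrays["zero_variance"] = model.standardization.zero_variance
    meta = {
        "n_layers": len(model.weights),
        "config": asdict(model.config),
        "registry_hash": model.registry_hash,
        "history": model.history,
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config_dict = meta["config"]
        config_dict["hidden_sizes"] = tuple(config_dict["hidden_sizes"])
        config = ModelConfig(**config_dict)
        weights = [
            (data[f"W{i}"], data[f"b{i}"]) for i in range(meta["n_layers"])
        ]
        params = StandardizationParams(
            mean=data["mean"], sd=data["sd"], zero_variance=data["zero_variance"]
        )
    return TrainedModel(
        weights=weights,
        standardization=params,
        config=config,
        registry_hash=meta["registry_hash"],
        history=meta["history"],
    )
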