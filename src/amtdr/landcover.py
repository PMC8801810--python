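"""Multilayer-perceptron land-cover classification.

Maps the 15-element spectral-temporal feature vector of each pixel-year
({NIRv, DI, TC1, TC2, TC3} x {growing-season max, min, mean}) to one of
four classes (grassland, forest, bare soil, water), producing annual
class maps.  The network is a small fully connected MLP — default two
hidden layers of 64 ReLU units and a softmax output — trained with
softmax cross-entropy loss and an Adam optimiser on a stratified 80/20
train/validation split.  Everything is plain NumPy: training is exactly
reproducible from the seed, logits are exposed for the loss function,
and models serialise to a single portable JSON file (weights + config +
feature scaler + seed fingerprint).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .containers import CLASS_NAMES

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "cross_entropy_loss",
    "train",
    "predict_map",
    "area_statistics",
]


@dataclass(frozen=True)
class ClassifierConfig:
    n_features: int = 15
    n_classes: int = 4
    hidden_layers: tuple = (64, 64)
    activation: str = "relu"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 64
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.activation not in ("relu", "tanh"):
            raise ValueError("activation must be 'relu' or 'tanh'")
        if self.n_features < 1 or self.n_classes < 2:
            raise ValueError("invalid layer sizes")


def _softmax_logsumexp(x: np.ndarray) -> np.ndarray:
    m = np.max(x, axis=-1, keepdims=True)
    return (m + np.log(np.sum(np.exp(x - m), axis=-1, keepdims=True)))[..., 0]


def cross_entropy_loss(logits: np.ndarray, true_class) -> float | np.ndarray:
    """Softmax cross-entropy: ``-x[class] + log sum_j exp(x[j])``.

    Overflow-safe via max-shifting.  ``logits`` may be one vector or a
    batch ``(n, k)``; ``true_class`` an int or an int array.  Batch
    input returns the mean loss.
    """
    x = np.asarray(logits, dtype=float)
    c = np.asarray(true_class)
    if not np.all(np.isfinite(x)):
        raise ValueError("logits must be finite")
    if x.ndim == 1:
        if not 0 <= int(c) < x.size:
            raise IndexError("class index out of range")
        return float(_softmax_logsumexp(x) - x[int(c)])
    if np.any(c < 0) or np.any(c >= x.shape[1]):
        raise IndexError("class index out of range")
    lse = _softmax_logsumexp(x)
    return float(np.mean(lse - x[np.arange(x.shape[0]), c]))


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(z, 0.0) if kind == "relu" else np.tanh(z)


def _activate_grad(a: np.ndarray, kind: str) -> np.ndarray:
    return (a > 0).astype(float) if kind == "relu" else 1.0 - a**2


@dataclass
class TrainedModel:
    """Weights, scaler and training provenance of a fitted MLP."""

    config: ClassifierConfig
    weights: list  # list of (W, b) per layer
    classes: list  # class codes in output order
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    loss_log: list = field(default_factory=list)
    holdout_accuracy: float = float("nan")

    def _forward(self, x: np.ndarray) -> np.ndarray:
        a = (np.asarray(x, dtype=float) - self.scaler_mean) / self.scaler_sd
        for W, b in self.weights[:-1]:
            a = _activate(a @ W + b, self.config.activation)
        W, b = self.weights[-1]
        return a @ W + b

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.atleast_2d(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class codes; argmax over logits, ties to the lowest code."""
        logits = self.predict_logits(x)
        return np.asarray(self.classes)[np.argmax(logits, axis=1)]

    def save(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "classes": [int(c) for c in self.classes],
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "loss_log": self.loss_log,
            "holdout_accuracy": self.holdout_accuracy,
            "weights": [[W.tolist(), b.tolist()] for W, b in self.weights],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        raw = json.loads(Path(path).read_text())
        cfg = raw["config"]
        cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
        return cls(
            config=ClassifierConfig(**cfg),
            weights=[(np.array(W), np.array(b)) for W, b in raw["weights"]],
            classes=list(raw["classes"]),
            scaler_mean=np.array(raw["scaler_mean"]),
            scaler_sd=np.array(raw["scaler_sd"]),
            loss_log=raw["loss_log"],
            holdout_accuracy=raw["holdout_accuracy"],
        )


def _stratified_split(labels: np.ndarray, train_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for code in np.unique(labels):
        idx = np.flatnonzero(labels == code)
        rng.shuffle(idx)
        k = int(round(train_fraction * idx.size))
        k = min(max(k, 1), idx.size - 1) if idx.size > 1 else idx.size
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def train(
    features: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig | None = None,
) -> TrainedModel:
    """Fit the MLP on labelled feature vectors.

    ``features`` is ``(n_samples, n_features)``; ``labels`` integer
    class codes.  A stratified ``train_fraction`` split is held out and
    scored (``holdout_accuracy``); feature z-scoring uses training-split
    statistics only.  ``loss_log`` records the full-training-set
    cross-entropy after every epoch.
    """
    if config is None:
        config = ClassifierConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    if x.shape[1] != config.n_features:
        raise ValueError(
            f"feature width {x.shape[1]} does not match config ({config.n_features})"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite; filter incomplete records first")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least two classes")
    if classes.size != config.n_classes:
        config = ClassifierConfig(**{**asdict(config), "n_classes": int(classes.size)})
    class_index = {c: i for i, c in enumerate(classes.tolist())}
    y_idx = np.array([class_index[v] for v in y.tolist()])

    rng = np.random.default_rng(config.seed)
    tr, te = _stratified_split(y_idx, config.train_fraction, rng)
    x_tr, y_tr = x[tr], y_idx[tr]
    x_te, y_te = x[te], y_idx[te]

    mean = x_tr.mean(axis=0)
    sd = x_tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x_tr - mean) / sd

    sizes = [config.n_features, *config.hidden_layers, int(classes.size)]
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(
            (rng.uniform(-limit, limit, size=(fan_in, fan_out)), np.zeros(fan_out))
        )

    # Adam state
    m_state = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    v_state = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = xs.shape[0]
    loss_log = []

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = xs[batch], y_tr[batch]
            # forward
            acts = [xb]
            a = xb
            for W, b in weights[:-1]:
                a = _activate(a @ W + b, config.activation)
                acts.append(a)
            W, b = weights[-1]
            logits = a @ W + b
            # softmax gradient
            shifted = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(shifted)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(yb.size), yb] -= 1.0
            delta = p / yb.size
            # backward
            grads = []
            for li in range(len(weights) - 1, -1, -1):
                gW = acts[li].T @ delta
                gb = delta.sum(axis=0)
                grads.append((gW, gb))
                if li > 0:
                    delta = (delta @ weights[li][0].T) * _activate_grad(
                        acts[li], config.activation
                    )
            grads.reverse()
            # Adam update
            step += 1
            for li, ((gW, gb), (W, b)) in enumerate(zip(grads, weights)):
                mW, mb = m_state[li]
                vW, vb = v_state[li]
                mW = beta1 * mW + (1 - beta1) * gW
                mb = beta1 * mb + (1 - beta1) * gb
                vW = beta2 * vW + (1 - beta2) * gW**2
                vb = beta2 * vb + (1 - beta2) * gb**2
                m_state[li] = (mW, mb)
                v_state[li] = (vW, vb)
                corr1 = 1 - beta1**step
                corr2 = 1 - beta2**step
                weights[li] = (
                    W - config.learning_rate * (mW / corr1) / (np.sqrt(vW / corr2) + eps),
                    b - config.learning_rate * (mb / corr1) / (np.sqrt(vb / corr2) + eps),
                )
        # epoch loss on the full training split
        a = xs
        for W, b in weights[:-1]:
            a = _activate(a @ W + b, config.activation)
        logits = a @ weights[-1][0] + weights[-1][1]
        loss_log.append(cross_entropy_loss(logits, y_tr))

    model = TrainedModel(
        config=config,
        weights=weights,
        classes=classes.tolist(),
        scaler_mean=mean,
        scaler_sd=sd,
        loss_log=loss_log,
    )
    if x_te.shape[0]:
        pred = model.predict(x_te)
        model.holdout_accuracy = float(np.mean(pred == classes[y_te]))
    return model


def predict_map(
    model: TrainedModel,
    feature_grids: dict,
    feature_names: list,
) -> np.ndarray:
    """Classify one year's feature grids into an annual class map.

    ``feature_grids`` maps feature name -> (rows, cols) grid and must
    contain a boolean ``valid`` grid; invalid pixels get the nodata
    code 0.
    """
    if len(feature_names) != model.config.n_features:
        raise ValueError("feature list width does not match the model")
    valid = np.asarray(feature_grids["valid"], dtype=bool)
    rows, cols = valid.shape
    xmat = np.stack([np.asarray(feature_grids[n], dtype=float).ravel() for n in feature_names], axis=1)
    out = np.zeros(rows * cols, dtype=np.int16)
    sel = valid.ravel() & np.all(np.isfinite(xmat), axis=1)
    if np.any(sel):
        out[sel] = model.predict(xmat[sel])
    return out.reshape(rows, cols)


def area_statistics(
    maps: dict[int, np.ndarray] | list,
    pixel_area_km2: float = 0.25,
    class_codes: dict | None = None,
) -> "pd.DataFrame":
    """Per-year class areas and fractions from annual class maps.

    Area = pixel count x pixel area; fraction = area / total mapped
    area (nodata excluded from class areas but included in the grid
    total).  ``pixel_area_km2`` defaults to a 500-m pixel.
    """
    import pandas as pd

    if isinstance(maps, dict):
        items = sorted(maps.items())
    else:
        items = list(enumerate(maps))
    if not items:
        raise ValueError("no maps supplied")
    shape = np.asarray(items[0][1]).shape
    codes = sorted(CLASS_NAMES) if class_codes is None else sorted(class_codes)
    rows = []
    for year, cmap in items:
        cmap = np.asarray(cmap)
        if cmap.shape != shape:
            raise ValueError("maps must share one grid")
        total_area = cmap.size * pixel_area_km2
        for code in codes:
            count = int(np.sum(cmap == code))
            area = count * pixel_area_km2
            rows.append(
                {
                    "year": year,
                    "class_code": code,
                    "class_name": CLASS_NAMES.get(code, str(code)),
                    "pixel_count": count,
                    "area_km2": area,
                    "fraction_pct": 100.0 * area / total_area,
                }
            )
    return pd.DataFrame(rows)


def relative_change_pct(a1: float, a2: float) -> float:
    """Relative change between two areas, in percent: (A2-A1)/A1 x 100."""
    if a1 == 0:
        raise ValueError("baseline area is zero")
    return (a2 - a1) / a1 * 100.0
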