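"""Fully-connected tumor/normal classifiers.

The architecture mirrors the published models: an input layer over normalized
abundances, hidden layers of 400 and 100 units for the mRNA model (plus an
extra 40-unit layer for the ceRNA model), ReLU activations, an optional
per-feature normalization (batch norm) after each hidden layer, and a single
sigmoid output unit. Training uses Adam (default moments), binary
cross-entropy, batch size 16 and learning rate 1e-4, on a stratified 70/30
train/validation split; the split can be repeated to gauge stability.

The network is implemented directly on numpy so that training is bit-exact
under a fixed seed on one thread and so the attribution engine can traverse
the exact layer structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

_BN_EPS = 1e-3
_BN_MOMENTUM = 0.99
_ADAM_EPS = 1e-7


@dataclass
class ModelSpec:
    n_features: int
    hidden_sizes: tuple = (400, 100)
    use_regularization: bool = True   # batch norm after each hidden layer
    activation: str = "relu"
    l2: float = 0.0                   # optional weight penalty alternative

    def validate(self) -> None:
        if self.n_features <= 0:
            raise ValueError(f"n_features must be positive, got {self.n_features}")
        if not self.hidden_sizes or any(h <= 0 for h in self.hidden_sizes):
            raise ValueError(f"hidden_sizes must be non-empty and positive, got {self.hidden_sizes}")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")


@dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 200                 # reference protocol uses >= 1000
    learning_rate: float = 1e-4
    split_fraction: float = 0.7
    n_repeats: int = 50
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise ValueError(f"split_fraction must lie in (0,1), got {self.split_fraction}")
        if self.batch_size < 1 or self.epochs < 0 or self.n_repeats < 1:
            raise ValueError("batch_size/epochs/n_repeats out of range")


class Dense:
    def __init__(self, weight: np.ndarray, bias: np.ndarray):
        self.weight = weight
        self.bias = bias

    def forward(self, x, training=False):
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, dout):
        self.d_weight = self._x.T @ dout
        self.d_bias = dout.sum(axis=0)
        return dout @ self.weight.T

    def params(self):
        return [("weight", self.weight, "d_weight"), ("bias", self.bias, "d_bias")]


class BatchNorm:
    """Per-unit normalization; affine (running-stat) transform at inference."""

    def __init__(self, size: int):
        self.gamma = np.ones(size)
        self.beta = np.zeros(size)
        self.running_mean = np.zeros(size)
        self.running_var = np.ones(size)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = _BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mean
            self.running_var = _BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var
            self._xc = x - mean
            self._inv = 1.0 / np.sqrt(var + _BN_EPS)
            self._xn = self._xc * self._inv
            return self.gamma * self._xn + self.beta
        xn = (x - self.running_mean) / np.sqrt(self.running_var + _BN_EPS)
        return self.gamma * xn + self.beta

    def backward(self, dout):
        m = dout.shape[0]
        self.d_gamma = (dout * self._xn).sum(axis=0)
        self.d_beta = dout.sum(axis=0)
        dxn = dout * self.gamma
        dvar = (dxn * self._xc).sum(axis=0) * -0.5 * self._inv**3
        dmean = -(dxn * self._inv).sum(axis=0) + dvar * (-2.0 / m) * self._xc.sum(axis=0)
        return dxn * self._inv + dvar * 2.0 * self._xc / m + dmean / m

    def inference_affine(self):
        """(scale, shift) of the inference-time per-unit affine map."""
        scale = self.gamma / np.sqrt(self.running_var + _BN_EPS)
        return scale, self.beta - self.running_mean * scale

    def params(self):
        return [("gamma", self.gamma, "d_gamma"), ("beta", self.beta, "d_beta")]


class ReLU:
    def forward(self, x, training=False):
        self._x = x
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * (self._x > 0)

    def params(self):
        return []


class Sigmoid:
    def forward(self, x, training=False):
        return 1.0 / (1.0 + np.exp(-x))

    def params(self):
        return []


class Model:
    """A feed-forward classifier with an explicit layer list."""

    def __init__(self, layers: list, spec: ModelSpec | None = None):
        self.layers = layers
        self.spec = spec

    @property
    def n_params(self) -> int:
        return sum(p[1].size for layer in self.layers for p in layer.params())

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def predict_proba(self, x) -> np.ndarray:
        return np.asarray(self.forward(np.asarray(x, dtype=float))).ravel()

    def predict_logit(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        for layer in self.layers:
            if isinstance(layer, Sigmoid):
                break
            x = layer.forward(x)
        return x.ravel()


def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Deterministically initialized network (He-normal weights, zero biases)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    layers: list = []
    fan_in = spec.n_features
    for width in spec.hidden_sizes:
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, width))
        layers.append(Dense(w, np.zeros(width)))
        if spec.use_regularization:
            layers.append(BatchNorm(width))
        layers.append(ReLU())
        fan_in = width
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, 1))
    layers.append(Dense(w, np.zeros(1)))
    layers.append(Sigmoid())
    return Model(layers, spec)


def stratified_split(y: np.ndarray, fraction: float, rng) -> tuple:
    """Index split keeping the class ratio; returns (train_idx, val_idx)."""
    train, val = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        k = int(round(fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train.append(idx[:k])
        val.append(idx[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(val))


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class TrainResult:
    model: Model
    history: pd.DataFrame          # epoch, train_loss, train_acc, val_loss, val_acc
    train_idx: np.ndarray
    val_idx: np.ndarray
    final: dict = field(default_factory=dict)


class _Adam:
    def __init__(self, model: Model, lr: float):
        self.lr = lr
        self.t = 0
        self.state = {}
        self.model = model

    def step(self, l2: float = 0.0) -> None:
        self.t += 1
        b1, b2 = 0.9, 0.999
        for li, layer in enumerate(self.model.layers):
            for name, value, gname in layer.params():
                grad = getattr(layer, gname)
                if l2 and name == "weight":
                    grad = grad + l2 * value
                key = (li, name)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(value), np.zeros_like(value))
                m, v = self.state[key]
                m = b1 * m + (1 - b1) * grad
                v = b2 * v + (1 - b2) * grad**2
                self.state[key] = (m, v)
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                value -= self.lr * mhat / (np.sqrt(vhat) + _ADAM_EPS)


def train(
    model: Model,
    X,
    y,
    config: TrainConfig,
    repeat: int = 0,
) -> TrainResult:
    """Train on a stratified split; per-epoch accuracy/loss curves for both sets.

    The split and minibatch order derive from ``(config.seed, repeat)``, so a
    designated repeat is reproducible and repeats are independent.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    rng = np.random.default_rng([config.seed, repeat])
    train_idx, val_idx = stratified_split(y, config.split_fraction, rng)
    Xt, yt = X[train_idx], y[train_idx]
    Xv, yv = X[val_idx], y[val_idx]
    if config.batch_size > Xt.shape[0]:
        raise ValueError(
            f"batch_size {config.batch_size} exceeds training-set size {Xt.shape[0]}"
        )
    opt = _Adam(model, config.learning_rate)
    l2 = model.spec.l2 if model.spec is not None else 0.0
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(Xt.shape[0])
        for start in range(0, Xt.shape[0], config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = Xt[batch], yt[batch]
            p = model.forward(xb, training=True).ravel()
            p = np.clip(p, 1e-7, 1 - 1e-7)
            dout = ((p - yb) / xb.shape[0])[:, None]
            for layer in reversed(model.layers[:-1]):  # sigmoid folded into dout
                dout = layer.backward(dout)
            opt.step(l2=l2)
        pt = model.predict_proba(Xt)
        pv = model.predict_proba(Xv)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": bce_loss(pt, yt),
                "train_acc": float(np.mean((pt > 0.5) == yt)),
                "val_loss": bce_loss(pv, yv),
                "val_acc": float(np.mean((pv > 0.5) == yv)),
            }
        )
    history = pd.DataFrame(rows, columns=["epoch", "train_loss", "train_acc", "val_loss", "val_acc"])
    final = dict(history.iloc[-1]) if len(history) else {}
    return TrainResult(model=model, history=history, train_idx=train_idx, val_idx=val_idx, final=final)


def train_repeats(spec: ModelSpec, X, y, config: TrainConfig) -> tuple:
    """Repeat the split/train protocol ``config.n_repeats`` times.

    Returns ``(designated TrainResult of repeat 0, per-repeat final metrics)``.
    """
    results = []
    designated = None
    for repeat in range(config.n_repeats):
        model = build_model(spec, seed=config.seed + repeat)
        res = train(model, X, y, config, repeat=repeat)
        if repeat == 0:
            designated = res
        results.append({"repeat": repeat, **res.final})
    return designated, pd.DataFrame(results)


def evaluate_roc(scores_or_model, X, y) -> tuple:
    """ROC points and trapezoid AUC for a model (or raw scores, X=None)."""
    y = np.asarray(y, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise ValueError("ROC undefined: y must contain both classes")
    if hasattr(scores_or_model, "predict_proba") and X is not None:
        scores = np.asarray(scores_or_model.predict_proba(X), dtype=float).ravel()
    else:
        scores = np.asarray(scores_or_model, dtype=float).ravel()
    fpr, tpr, thresholds = roc_curve(y, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, float(sk_auc(fpr, tpr))


BASELINE_METHODS = (
    "knn",
    "svm",
    "decision_tree",
    "naive_bayes",
    "logistic_regression",
    "random_forest",
)


def baseline_classifiers(X, y, seed: int = 0, split_fraction: float = 0.7) -> pd.DataFrame:
    """Validation AUC of six classical classifiers under the same split protocol."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    rng = np.random.default_rng([seed, 0])
    train_idx, val_idx = stratified_split(y, split_fraction, rng)
    Xt, yt, Xv, yv = X[train_idx], y[train_idx], X[val_idx], y[val_idx]
    models = {
        "knn": KNeighborsClassifier(),
        "svm": SVC(random_state=seed),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "naive_bayes": GaussianNB(),
        "logistic_regression": LogisticRegression(max_iter=2000, random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed),
    }
    rows = []
    for name in BASELINE_METHODS:
        clf = models[name].fit(Xt, yt)
        if hasattr(clf, "decision_function"):
            scores = clf.decision_function(Xv)
        else:
            scores = clf.predict_proba(Xv)[:, 1]
        _, auc_val = evaluate_roc(scores, None, yv)
        rows.append({"method": name, "auc": auc_val})
    return pd.DataFrame(rows).set_index("method")
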