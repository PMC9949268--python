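"""The 14-layer fully connected network: initialization, forward pass,
binary cross-entropy training with Adam, checkpointing, and frozen-weight
transfer application.

Counting convention: 14 layers = input + 12 hidden + output, i.e. 13
weight matrices. The output unit has a logistic link, so predictions are
per-variant association probabilities in (0, 1). Dropout is active only
during training; inference is deterministic. Everything is plain NumPy:
gradients are hand-derived backpropagation, checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from deepgwas.training import Scaler, stratified_split

EPS = 1e-12
CHECKPOINT_VERSION = 1

DEFAULT_HIDDEN = (256, 256, 128, 128, 128, 64, 64, 64, 32, 32, 16, 8)


@dataclass
class NetworkConfig:
    input_width: int = 33
    hidden_widths: tuple[int, ...] = DEFAULT_HIDDEN
    activation: str = "relu"
    dropout_rate: float = 0.1

    def __post_init__(self):
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if self.input_width < 1 or any(w < 1 for w in self.hidden_widths):
            raise ValueError("all layer widths must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")

    @property
    def n_layers(self) -> int:
        return len(self.hidden_widths) + 2  # input + hidden + output

    @property
    def widths(self) -> list[int]:
        return [self.input_width, *self.hidden_widths, 1]


@dataclass
class TrainingHyper:
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0
    val_fraction: float = 0.1

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("all training hyperparameters must be positive")


@dataclass
class ModelState:
    """Architecture, learned weights, standardization parameters, metadata."""

    config: NetworkConfig
    weights: list[np.ndarray]  # W_1..W_13, shape (fan_in, fan_out)
    biases: list[np.ndarray]
    scaler: Scaler | None = None
    feature_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        widths = self.config.widths
        if len(self.weights) != len(widths) - 1:
            raise ValueError("weight tensor count inconsistent with config")
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (widths[i], widths[i + 1]) or b.shape != (widths[i + 1],):
                raise ValueError(f"layer {i}: tensor shape inconsistent with config")

    def checksum(self) -> str:
        h = hashlib.sha256()
        for W, b in zip(self.weights, self.biases):
            h.update(np.ascontiguousarray(W).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
        return h.hexdigest()


class CheckpointError(IOError):
    """Unreadable, truncated, or version-mismatched model checkpoint."""


def init_model(
    config: NetworkConfig, seed: int = 0, feature_names: list[str] | None = None
) -> ModelState:
    """Variance-scaled uniform (He) initialization, deterministic given seed."""
    if feature_names is not None and len(feature_names) != config.input_width:
        raise ValueError(
            f"feature schema length {len(feature_names)} != input width "
            f"{config.input_width}"
        )
    rng = np.random.default_rng(seed)
    widths = config.widths
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return ModelState(config, weights, biases, feature_names=feature_names,
                      meta={"init_seed": int(seed)})


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_full(model: ModelState, X: np.ndarray, dropout_masks=None):
    """Forward pass returning probabilities and per-layer activations."""
    a = X
    acts = [a]
    n_layers = len(model.weights)
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        if i < n_layers - 1:
            a = np.maximum(z, 0.0)
            if dropout_masks is not None:
                a = a * dropout_masks[i]
        else:
            a = _sigmoid(z)
        acts.append(a)
    p = np.clip(acts[-1][:, 0], EPS, 1.0 - EPS)
    return p, acts


def forward(model: ModelState, X) -> np.ndarray:
    """Predicted association probabilities P̂ in (0, 1); dropout off."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != model.config.input_width:
        raise ValueError(
            f"input has {arr.shape[-1] if arr.ndim == 2 else '?'} columns, "
            f"model expects {model.config.input_width}"
        )
    bad = ~np.isfinite(arr).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite feature values at rows {np.flatnonzero(bad)[:10]}")
    p, _ = _forward_full(model, arr)
    return p


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = EPS) -> float:
    """Mean binary cross entropy −(1/n) Σ [y log p + (1−y) log(1−p)]."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


def loss_and_grad(model: ModelState, X: np.ndarray, y: np.ndarray, dropout_masks=None):
    """BCE loss and its gradients w.r.t. every weight and bias.

    Uses the logit-space shortcut d loss/d z_out = (p − y)/n, which is the
    exact gradient of the clipped loss whenever p is away from the clip
    boundaries.
    """
    n = len(y)
    p, acts = _forward_full(model, X, dropout_masks)
    loss = bce_loss(p, y)
    grads_W = [None] * len(model.weights)
    grads_b = [None] * len(model.biases)
    delta = ((p - y) / n)[:, None]  # gradient at the output pre-activation
    for i in range(len(model.weights) - 1, -1, -1):
        a_prev = acts[i]
        grads_W[i] = a_prev.T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = delta @ model.weights[i].T
            if dropout_masks is not None:
                delta = delta * dropout_masks[i - 1]
            delta = delta * (acts[i] > 0)
    return loss, grads_W, grads_b


class _Adam:
    """Adaptive-moment minibatch optimizer (standard defaults)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(
    model: ModelState,
    X,
    y: np.ndarray,
    hyper: TrainingHyper | None = None,
) -> tuple[ModelState, dict]:
    """Minibatch Adam on binary cross entropy with early stopping.

    ``X`` must already be standardized with the scaler the model will
    carry. A label-stratified 10% split is held out; training stops when
    validation loss fails to improve for ``patience`` epochs and the
    best-validation weights are restored. Fully reproducible given
    ``hyper.seed``.
    """
    hyper = hyper or TrainingHyper()
    arr = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("training requires both classes present")
    rng = np.random.default_rng(hyper.seed)
    tr_idx, val_idx = stratified_split(y, hyper.val_fraction, hyper.seed)
    X_tr, y_tr = arr[tr_idx], y[tr_idx]
    X_val, y_val = arr[val_idx], y[val_idx]

    params = model.weights + model.biases
    opt = _Adam(params, lr=hyper.learning_rate)
    n_hidden = len(model.weights) - 1
    rate = model.config.dropout_rate
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = None
    stall = 0
    widths = model.config.widths

    for epoch in range(hyper.max_epochs):
        order = rng.permutation(len(y_tr))
        epoch_loss = 0.0
        for s in range(0, len(order), hyper.batch_size):
            batch = order[s : s + hyper.batch_size]
            masks = None
            if rate > 0:
                masks = [
                    (rng.random((len(batch), widths[i + 1])) >= rate) / (1.0 - rate)
                    for i in range(n_hidden)
                ]
            loss, gW, gb = loss_and_grad(model, X_tr[batch], y_tr[batch], masks)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            epoch_loss += loss * len(batch)
            opt.step(params, gW + gb)
        history["train_loss"].append(epoch_loss / len(y_tr))
        val_loss = bce_loss(_forward_full(model, X_val)[0], y_val)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = ([W.copy() for W in model.weights],
                            [b.copy() for b in model.biases])
            stall = 0
        else:
            stall += 1
            if stall >= hyper.patience:
                break
    if best_weights is not None:
        model.weights, model.biases = best_weights
    model.meta.update(
        {
            "train_seed": int(hyper.seed),
            "epochs_run": len(history["train_loss"]),
            "best_val_loss": float(best_val),
            "final_train_loss": float(history["train_loss"][-1]),
        }
    )
    return model, history


def predict_proba(model: ModelState, X: pd.DataFrame) -> np.ndarray:
    """Standardize raw features with the model's stored scaler and predict."""
    if model.scaler is None:
        raise ValueError("model carries no standardization parameters")
    return forward(model, model.scaler.transform(X).to_numpy())


def transfer_apply(model: ModelState, X_new: pd.DataFrame) -> np.ndarray:
    """Apply a trained model to another trait's features with frozen weights.

    Pure inference: weights are byte-identical before and after (asserted
    via checksum). The new feature matrix must use the identical schema.
    """
    if model.feature_names is not None and list(X_new.columns) != model.feature_names:
        diff = set(X_new.columns) ^ set(model.feature_names)
        raise ValueError(f"feature schema mismatch; differing columns: {sorted(diff)}")
    before = model.checksum()
    p = predict_proba(model, X_new) if model.scaler is not None else forward(
        model, np.asarray(X_new, dtype=float)
    )
    assert model.checksum() == before, "weights changed during transfer application"
    return p


def save_model(model: ModelState, path) -> None:
    """Write a self-describing checkpoint (zip of arrays + JSON header)."""
    arrays = {}
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W_{i:02d}"] = W
        arrays[f"b_{i:02d}"] = b
    header = {
        "format_version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "feature_names": model.feature_names,
        "meta": model.meta,
        "has_scaler": model.scaler is not None,
    }
    if model.scaler is not None:
        arrays["scaler_mean"] = model.scaler.mean
        arrays["scaler_sd"] = model.scaler.sd
        arrays["scaler_constant"] = model.scaler.constant
        header["scaler_features"] = model.scaler.feature_names
    buf = io.BytesIO()
    np.savez(buf, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_model(path) -> ModelState:
    """Load a checkpoint; predictions reproduce bit-identically."""
    try:
        with np.load(path) as npz:
            header = json.loads(bytes(npz["header"]).decode())
            if header.get("format_version") != CHECKPOINT_VERSION:
                raise CheckpointError(
                    f"checkpoint version {header.get('format_version')} != "
                    f"{CHECKPOINT_VERSION}"
                )
            cfg = header["config"]
            cfg["hidden_widths"] = tuple(cfg["hidden_widths"])
            config = NetworkConfig(**cfg)
            n = len(config.widths) - 1
            weights = [npz[f"W_{i:02d}"] for i in range(n)]
            biases = [npz[f"b_{i:02d}"] for i in range(n)]
            scaler = None
            if header["has_scaler"]:
                scaler = Scaler(
                    header["scaler_features"],
                    npz["scaler_mean"],
                    npz["scaler_sd"],
                    npz["scaler_constant"],
                )
    except (zipfile.BadZipFile, KeyError, OSError, ValueError) as exc:
        if isinstance(exc, CheckpointError):
            raise
        raise CheckpointError(f"unreadable or truncated checkpoint {path}: {exc}") from exc
    return ModelState(config, weights, biases, scaler=scaler,
                      feature_names=header["feature_names"], meta=header["meta"])
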