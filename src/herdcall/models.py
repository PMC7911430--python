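"""CNN classifiers and a from-scratch Adadelta optimizer.

Two convolutional classifiers share one small, self-contained numpy
framework: a binary gate separating cattle voice from other barn sounds,
and a deeper 4-class model mapping a cattle call to a behavioral class
(0 estrus, 1 food-anticipating, 2 cough, 3 normal).  Both take the
fixed-size Mel-cepstral matrix from :mod:`herdcall.features` as a single
input channel and end in a Softmax layer; hidden activations are ReLU.

Parameters are updated with Adadelta, which needs no learning rate: it
scales each raw gradient by the ratio of the running RMS of past updates to
the running RMS of past gradients,

    E[g^2]_t      = gamma E[g^2]_{t-1}      + (1 - gamma) g_t^2
    delta_t       = - sqrt(E[dx^2]_{t-1} + eps) / sqrt(E[g^2]_t + eps) * g_t
    E[dx^2]_t     = gamma E[dx^2]_{t-1}     + (1 - gamma) delta_t^2
    theta_{t+1}   = theta_t + delta_t

with gamma = 0.95 and eps = 1e-7 by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .config import (
    DEFAULT_ADADELTA_EPSILON,
    DEFAULT_ADADELTA_GAMMA,
    DEFAULT_BATCH_SIZE,
    DEFAULT_EPOCHS,
    DEFAULT_VALIDATION_FRACTION,
)
from .exceptions import ConfigError, DataError, ShapeError

__all__ = [
    "AdadeltaState",
    "adadelta_step",
    "AdadeltaOptimizer",
    "CNNSpec",
    "TrainConfig",
    "SequentialCNN",
    "build_binary_cnn",
    "build_behavior_cnn",
    "train",
    "predict",
    "TrainingHistory",
]


# ---------------------------------------------------------------------------
# Adadelta
# ---------------------------------------------------------------------------

@dataclass
class AdadeltaState:
    """Parameter vector plus the two Adadelta accumulators."""

    theta: np.ndarray
    accum_grad_sq: np.ndarray = None
    accum_update_sq: np.ndarray = None
    gamma: float = DEFAULT_ADADELTA_GAMMA
    epsilon: float = DEFAULT_ADADELTA_EPSILON
    t: int = 0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.accum_grad_sq is None:
            self.accum_grad_sq = np.zeros_like(self.theta)
        if self.accum_update_sq is None:
            self.accum_update_sq = np.zeros_like(self.theta)
        if not (0.0 < self.gamma < 1.0):
            raise ConfigError("gamma must lie in (0, 1)")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")


def _adadelta_delta(g, accum_grad_sq, accum_update_sq, gamma, epsilon):
    """One Adadelta update: returns (delta, new E[g^2], new E[dx^2])."""
    eg2 = gamma * accum_grad_sq + (1.0 - gamma) * g * g
    delta = -np.sqrt(accum_update_sq + epsilon) / np.sqrt(eg2 + epsilon) * g
    edx2 = gamma * accum_update_sq + (1.0 - gamma) * delta * delta
    return delta, eg2, edx2


def adadelta_step(state: AdadeltaState, gradient: np.ndarray) -> AdadeltaState:
    """Apply one Adadelta update to the state; returns a new state.

    The first step from zero accumulators gives
    delta = -sqrt(eps) / sqrt((1-gamma) g^2 + eps) * g.
    """
    g = np.asarray(gradient, dtype=np.float64)
    if g.shape != state.theta.shape:
        raise ShapeError("gradient shape does not match parameters")
    if not np.all(np.isfinite(g)):
        raise DataError("gradient contains NaN or infinite entries")
    delta, eg2, edx2 = _adadelta_delta(
        g, state.accum_grad_sq, state.accum_update_sq, state.gamma, state.epsilon
    )
    return AdadeltaState(
        theta=state.theta + delta,
        accum_grad_sq=eg2,
        accum_update_sq=edx2,
        gamma=state.gamma,
        epsilon=state.epsilon,
        t=state.t + 1,
    )


class AdadeltaOptimizer:
    """Adadelta over a list of parameter tensors (used by the training loop)."""

    def __init__(self, params: list[np.ndarray], gamma=DEFAULT_ADADELTA_GAMMA,
                 epsilon=DEFAULT_ADADELTA_EPSILON):
        self.gamma = float(gamma)
        self.epsilon = float(epsilon)
        self._eg2 = [np.zeros_like(p) for p in params]
        self._edx2 = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for i, (p, g) in enumerate(zip(params, grads)):
            delta, self._eg2[i], self._edx2[i] = _adadelta_delta(
                g, self._eg2[i], self._edx2[i], self.gamma, self.epsilon
            )
            p += delta


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class _Conv2D:
    """3x3 'same' convolution (stride 1) via im2col, single-precision."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, k: int = 3):
        self.k = k
        self.W = _he_init(rng, (out_ch, in_ch * k * k), in_ch * k * k)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b], [self.dW, self.db]

    def _cols(self, x):
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N, H, W, C*k*k)
        v = v.transpose(0, 2, 3, 1, 4, 5)
        N, H, W = v.shape[:3]
        return np.ascontiguousarray(v).reshape(N, H, W, -1)

    def forward(self, x, train=False):
        self._xshape = x.shape
        cols = self._cols(x)
        if train:
            self._cols_cache = cols
        N, H, W, _ = cols.shape
        out = cols @ self.W.T + self.b  # (N, H, W, F)
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout):
        N, F, H, W = dout.shape
        d = dout.transpose(0, 2, 3, 1).reshape(-1, F)  # (NHW, F)
        cols = self._cols_cache.reshape(-1, self.W.shape[1])
        self.dW[...] = d.T @ cols
        self.db[...] = d.sum(axis=0)
        dcols = (d @ self.W).reshape(N, H, W, -1)
        # scatter back to the padded input
        C = self._xshape[1]
        k, p = self.k, self.k // 2
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        dcols = dcols.reshape(N, H, W, C, k, k)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + self._xshape[2], p : p + self._xshape[3]]


class _ReLU:
    def params(self):
        return [], []

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2D:
    """Non-overlapping max pooling; trailing rows/cols beyond a full window
    are dropped (floor semantics)."""

    def __init__(self, pool: tuple[int, int]):
        self.ph, self.pw = pool

    def params(self):
        return [], []

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        Ho, Wo = H // self.ph, W // self.pw
        if Ho == 0 or Wo == 0:
            raise ShapeError(
                f"input {H}x{W} smaller than pooling window {self.ph}x{self.pw}"
            )
        xc = x[:, :, : Ho * self.ph, : Wo * self.pw]
        xr = xc.reshape(N, C, Ho, self.ph, Wo, self.pw)
        out = xr.max(axis=(3, 5))
        if train:
            self._xshape = x.shape
            self._argmask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, dout):
        N, C, H, W = self._xshape
        Ho, Wo = H // self.ph, W // self.pw
        # divide ties equally so gradient mass is conserved
        counts = self._argmask.sum(axis=(3, 5), keepdims=True)
        dxr = self._argmask * (dout[:, :, :, None, :, None] / counts)
        dx = np.zeros((N, C, H, W), dtype=np.float32)
        dx[:, :, : Ho * self.ph, : Wo * self.pw] = dxr.reshape(N, C, Ho * self.ph, Wo * self.pw)
        return dx


class _Flatten:
    def params(self):
        return [], []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b], [self.dW, self.db]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNNSpec:
    """Architecture description: conv blocks, dense widths, class count."""

    input_shape: tuple[int, int]  # (mel bands, time frames); 1 channel implied
    conv_blocks: tuple[tuple[int, tuple[int, int]], ...]  # (filters, pool) per block
    dense_units: tuple[int, ...]
    output_units: int

    def __post_init__(self) -> None:
        if self.output_units not in (2, 4):
            raise ConfigError("output_units must be 2 (gate) or 4 (behavior)")

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "conv_blocks": [[f, list(p)] for f, p in self.conv_blocks],
            "dense_units": list(self.dense_units),
            "output_units": self.output_units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CNNSpec":
        return cls(
            input_shape=tuple(d["input_shape"]),
            conv_blocks=tuple((f, tuple(p)) for f, p in d["conv_blocks"]),
            dense_units=tuple(d["dense_units"]),
            output_units=d["output_units"],
        )


@dataclass
class TrainConfig:
    """Training hyperparameters; the loss is categorical cross-entropy."""

    epochs: int = DEFAULT_EPOCHS
    batch_size: int = DEFAULT_BATCH_SIZE
    validation_fraction: float = DEFAULT_VALIDATION_FRACTION
    seed: int = 0
    gamma: float = DEFAULT_ADADELTA_GAMMA
    epsilon: float = DEFAULT_ADADELTA_EPSILON
    class_weights: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ConfigError("validation_fraction must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)


class SequentialCNN:
    """Plain feed-forward CNN: conv/ReLU/pool blocks, dense head, Softmax.

    Inputs are standardized with per-row (per-coefficient) statistics fitted
    on the training split and stored with the model, so a saved checkpoint
    is self-contained.
    """

    def __init__(self, spec: CNNSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        H, W = spec.input_shape
        layers: list = []
        in_ch = 1
        for filters, pool in spec.conv_blocks:
            layers += [_Conv2D(in_ch, filters, rng), _ReLU(), _MaxPool2D(pool)]
            H, W = H // pool[0], W // pool[1]
            if H == 0 or W == 0:
                raise ShapeError("input smaller than the receptive field after pooling")
            in_ch = filters
        layers.append(_Flatten())
        n_in = in_ch * H * W
        for units in spec.dense_units:
            layers += [_Dense(n_in, units, rng), _ReLU()]
            n_in = units
        layers.append(_Dense(n_in, spec.output_units, rng))
        self.layers = layers
        self.input_mean = np.zeros((spec.input_shape[0], 1), dtype=np.float32)
        self.input_std = np.ones((spec.input_shape[0], 1), dtype=np.float32)

    # -- parameters -------------------------------------------------------
    def parameters(self):
        params, grads = [], []
        for layer in self.layers:
            p, g = layer.params()
            params += p
            grads += g
        return params, grads

    def parameter_count(self) -> int:
        return sum(p.size for p in self.parameters()[0])

    def fit_input_scaling(self, x: np.ndarray) -> None:
        """Per-row standardization statistics from the training split."""
        mu = x.mean(axis=(0, 2))
        sd = x.std(axis=(0, 2))
        self.input_mean = mu[:, None].astype(np.float32)
        self.input_std = np.maximum(sd, 1e-6)[:, None].astype(np.float32)

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.spec.input_shape:
            raise ShapeError(
                f"feature shape {x.shape[1:]} does not match model input "
                f"{self.spec.input_shape}"
            )
        x = (x - self.input_mean[None]) / self.input_std[None]
        return x[:, None, :, :]  # add channel axis

    # -- forward/backward -------------------------------------------------
    def _logits(self, x4: np.ndarray, train: bool = False) -> np.ndarray:
        h = x4
        for layer in self.layers:
            h = layer.forward(h, train=train)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self._logits(self._prepare(x)).astype(np.float64))

    def _backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Weights as .npz next to a JSON sidecar describing the spec."""
        path = Path(path)
        params, _ = self.parameters()
        arrays = {f"p{i}": p for i, p in enumerate(params)}
        arrays["input_mean"] = self.input_mean
        arrays["input_std"] = self.input_std
        np.savez(path, **arrays)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({"spec": self.spec.to_dict()}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SequentialCNN":
        path = Path(path)
        if not path.exists() and path.with_suffix(".npz").exists():
            path = path.with_suffix(".npz")
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ConfigError(f"missing model sidecar {sidecar}")
        spec = CNNSpec.from_dict(json.loads(sidecar.read_text())["spec"])
        model = cls(spec, seed=0)
        data = np.load(path)
        params, _ = model.parameters()
        for i, p in enumerate(params):
            p[...] = data[f"p{i}"]
        model.input_mean = data["input_mean"]
        model.input_std = data["input_std"]
        return model


def build_binary_cnn(input_shape: tuple[int, int] = (128, 2000), seed: int = 0,
                     spec: CNNSpec | None = None) -> SequentialCNN:
    """Cattle-voice / other-sound gate: 3 conv blocks, 64-unit head, 2 classes."""
    spec = spec or CNNSpec(
        input_shape=tuple(input_shape),
        conv_blocks=((16, (2, 4)), (32, (2, 4)), (64, (2, 4))),
        dense_units=(64,),
        output_units=2,
    )
    return SequentialCNN(spec, seed=seed)


def build_behavior_cnn(input_shape: tuple[int, int] = (128, 2000), seed: int = 0,
                       spec: CNNSpec | None = None) -> SequentialCNN:
    """4-class behavioral model: deeper stack (4 blocks), 128-unit head."""
    spec = spec or CNNSpec(
        input_shape=tuple(input_shape),
        conv_blocks=((16, (2, 2)), (32, (2, 2)), (64, (2, 2)), (128, (2, 2))),
        dense_units=(128,),
        output_units=4,
    )
    return SequentialCNN(spec, seed=seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Deterministic stratified holdout: indices (train, val)."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(fraction * idx.size)))
        if n_val >= idx.size:
            raise DataError(f"class {cls} too small to split")
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def _evaluate(model: SequentialCNN, x: np.ndarray, y: np.ndarray,
              batch: int = 64) -> tuple[float, float]:
    losses, correct = [], 0
    for s in range(0, len(x), batch):
        probs = model.predict_proba(x[s : s + batch])
        yy = y[s : s + batch]
        losses.append(-np.log(probs[np.arange(len(yy)), yy] + 1e-12))
        correct += int((probs.argmax(axis=1) == yy).sum())
    return float(np.mean(np.concatenate(losses))), correct / len(x)


def train(
    model: SequentialCNN,
    features: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[SequentialCNN, TrainingHistory]:
    """Fit the model with Adadelta on a stratified train/validation split.

    ``features`` is (n_samples, mel bands, frames); ``labels`` integer class
    indices.  The history records per-epoch train/validation loss and
    accuracy; the fitted model is the final epoch (no early stopping).
    Bit-reproducible for a fixed config seed.
    """
    config = config or TrainConfig()
    x = np.asarray(features, dtype=np.float32)
    y = np.asarray(labels, dtype=np.int64)
    if x.ndim != 3 or x.shape[0] != y.shape[0]:
        raise ShapeError("features must be (n_samples, bands, frames) matching labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise DataError("training requires at least two classes")
    if np.any(y < 0) or np.any(y >= model.spec.output_units):
        raise DataError("label outside the model's class range")

    rng = np.random.default_rng(config.seed)
    tr, va = _stratified_split(y, config.validation_fraction, rng)
    x_tr, y_tr, x_va, y_va = x[tr], y[tr], x[va], y[va]
    model.fit_input_scaling(x_tr)

    weights = np.ones(model.spec.output_units, dtype=np.float64)
    if config.class_weights:
        for k, v in config.class_weights.items():
            weights[int(k)] = float(v)

    params, grads = model.parameters()
    opt = AdadeltaOptimizer(params, gamma=config.gamma, epsilon=config.epsilon)
    history = TrainingHistory()
    n = len(x_tr)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for s in range(0, n, config.batch_size):
            sel = order[s : s + config.batch_size]
            xb = model._prepare(x_tr[sel])
            yb = y_tr[sel]
            logits = model._logits(xb, train=True)
            probs = _softmax(logits.astype(np.float64))
            wb = weights[yb]
            ep_loss += float(np.sum(wb * -np.log(probs[np.arange(len(yb)), yb] + 1e-12)))
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits *= wb[:, None] / len(yb)
            model._backward(dlogits.astype(np.float32))
            opt.step(params, grads)
        val_loss, val_acc = _evaluate(model, x_va, y_va)
        history.train_loss.append(ep_loss / n)
        history.train_accuracy.append(ep_correct / n)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
    return model, history


def predict(model: SequentialCNN, mfcc) -> tuple[int, np.ndarray]:
    """Classify one feature matrix: (argmax class index, Softmax vector)."""
    coeffs = getattr(mfcc, "coefficients", mfcc)
    probs = model.predict_proba(np.asarray(coeffs, dtype=np.float32))[0]
    return int(np.argmax(probs)), probs
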