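"""Minimal NumPy backend for the 1-D convolutional classifier.

Implements exactly the layer set the model specification can express
(valid-mode Conv1D, ELU, group normalization, max-pooling, dropout,
flatten, dense, sigmoid) with manual backpropagation and SGD-with-momentum.
Binary cross-entropy is computed from logits for numerical stability; L2
penalties enter the loss as lambda * sum(w^2) per layer (so their gradient
contribution is 2 * lambda * w per update, mirroring common framework
semantics).

The model is tiny (a few thousand parameters) and the arrays small, so a
vectorised NumPy implementation is entirely adequate on one CPU.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .architecture import (
    ConvLayerSpec,
    DenseSpec,
    DropoutSpec,
    EluSpec,
    FlattenSpec,
    GroupNormSpec,
    MaxPoolSpec,
    ModelSpec,
    SigmoidSpec,
    TrainingConfig,
    infer_shapes,
)


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, computed stably from logits."""
    z = logits.ravel()
    y = y.ravel()
    # -log sigmoid(z) = softplus(-z); -log(1 - sigmoid(z)) = softplus(z)
    losses = y * np.logaddexp(0.0, -z) + (1.0 - y) * np.logaddexp(0.0, z)
    return float(losses.mean())


class _Layer:
    """Base class: parameter-free, shape-preserving by default."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def l2_penalty(self) -> float:
        return 0.0

    def add_l2_grads(self) -> None:
        pass


class Conv1D(_Layer):
    """Valid-mode 1-D convolution over (batch, length, channels) input."""

    def __init__(self, spec: ConvLayerSpec, c_in: int, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        k, f = spec.kernel_size, spec.filters
        fan_in, fan_out = k * c_in, k * f
        self.params = {
            "W": _glorot_uniform(rng, (k, c_in, f), fan_in, fan_out),
            "b": np.zeros(f),
        }

    def forward(self, x, training):
        k, s = self.spec.kernel_size, self.spec.stride
        # windows: (B, L_out, C_in, k)
        xw = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)[:, ::s]
        self._xw, self._in_shape = xw, x.shape
        return np.tensordot(xw, self.params["W"], axes=([2, 3], [1, 0])) + self.params["b"]

    def backward(self, dy):
        k, s = self.spec.kernel_size, self.spec.stride
        W = self.params["W"]
        # dW[j, c, f] = sum_{b,t} xw[b, t, c, j] * dy[b, t, f]
        dW = np.tensordot(self._xw, dy, axes=([0, 1], [0, 1]))  # (C_in, k, f)
        self.grads = {"W": dW.transpose(1, 0, 2), "b": dy.sum(axis=(0, 1))}
        dx = np.zeros(self._in_shape)
        L_out = dy.shape[1]
        for j in range(k):
            dx[:, j : j + s * L_out : s, :] += dy @ W[j].T
        return dx

    def l2_penalty(self):
        return self.spec.weight_l2 * float((self.params["W"] ** 2).sum()) + (
            self.spec.bias_l2 * float((self.params["b"] ** 2).sum())
        )

    def add_l2_grads(self):
        self.grads["W"] += 2.0 * self.spec.weight_l2 * self.params["W"]
        self.grads["b"] += 2.0 * self.spec.bias_l2 * self.params["b"]


class Elu(_Layer):
    def __init__(self, spec: EluSpec):
        super().__init__()
        self.alpha = spec.alpha

    def forward(self, x, training):
        y = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._deriv = np.where(x > 0, 1.0, y + self.alpha)
        return y

    def backward(self, dy):
        return dy * self._deriv


class GroupNorm(_Layer):
    """Normalizes within contiguous channel groups, per sample, over
    (length, channels-in-group); batch-size independent."""

    def __init__(self, spec: GroupNormSpec, c_in: int, rng: np.random.Generator):
        super().__init__()
        if c_in % spec.groups != 0:
            raise ValueError(f"{spec.groups} groups do not divide {c_in} channels")
        self.groups, self.eps, self.c_in = spec.groups, spec.eps, c_in
        self.params = {"gamma": np.ones(c_in), "beta": np.zeros(c_in)}

    def forward(self, x, training):
        B, L, C = x.shape
        g = self.groups
        xg = x.reshape(B, L, g, C // g)
        mean = xg.mean(axis=(1, 3), keepdims=True)
        var = xg.var(axis=(1, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (xg - mean) * inv_std
        self._xhat, self._inv_std, self._shape = xhat, inv_std, x.shape
        out = xhat.reshape(B, L, C) * self.params["gamma"] + self.params["beta"]
        return out

    def backward(self, dy):
        B, L, C = self._shape
        g = self.groups
        xhat = self._xhat
        self.grads = {
            "gamma": (dy * xhat.reshape(B, L, C)).sum(axis=(0, 1)),
            "beta": dy.sum(axis=(0, 1)),
        }
        dxhat = (dy * self.params["gamma"]).reshape(B, L, g, C // g)
        m1 = dxhat.mean(axis=(1, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 3), keepdims=True)
        dx = self._inv_std * (dxhat - m1 - xhat * m2)
        return dx.reshape(B, L, C)


class MaxPool1D(_Layer):
    def __init__(self, spec: MaxPoolSpec):
        super().__init__()
        self.pool, self.stride = spec.pool_size, spec.stride

    def forward(self, x, training):
        xw = np.lib.stride_tricks.sliding_window_view(x, self.pool, axis=1)
        xw = xw[:, :: self.stride]  # (B, L_out, C, pool)
        self._argmax = xw.argmax(axis=3)
        self._in_shape = x.shape
        return xw.max(axis=3)

    def backward(self, dy):
        B, L_out, C = dy.shape
        dx = np.zeros(self._in_shape)
        b_idx = np.arange(B)[:, None, None]
        c_idx = np.arange(C)[None, None, :]
        pos = np.arange(L_out)[None, :, None] * self.stride + self._argmax
        np.add.at(dx, (b_idx, pos, c_idx), dy)
        return dx


class Dropout(_Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, spec: DropoutSpec, rng: np.random.Generator):
        super().__init__()
        self.rate = spec.rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(_Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(_Layer):
    def __init__(self, spec: DenseSpec, n_in: int, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.params = {
            "W": _glorot_uniform(rng, (n_in, spec.units), n_in, spec.units),
            "b": np.zeros(spec.units),
        }

    def forward(self, x, training):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.spec.activation == "elu":
            y = np.where(z > 0, z, np.expm1(z))
            self._act_deriv = np.where(z > 0, 1.0, y + 1.0)
            return y
        self._act_deriv = None
        return z

    def backward(self, dy):
        if self._act_deriv is not None:
            dy = dy * self._act_deriv
        self.grads = {"W": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["W"].T

    def l2_penalty(self):
        return self.spec.weight_l2 * float((self.params["W"] ** 2).sum()) + (
            self.spec.bias_l2 * float((self.params["b"] ** 2).sum())
        )

    def add_l2_grads(self):
        self.grads["W"] += 2.0 * self.spec.weight_l2 * self.params["W"]
        self.grads["b"] += 2.0 * self.spec.bias_l2 * self.params["b"]


class Network:
    """A compiled model: ordered layers ending in a sigmoid output.

    Training uses SGD with momentum on mini-batches, monitors a validation
    metric each epoch, checkpoints the best weights, and stops early after
    ``early_stop_patience`` epochs without strict improvement.
    """

    def __init__(self, spec: ModelSpec, config: TrainingConfig):
        if not spec.layers or not isinstance(spec.layers[-1], SigmoidSpec):
            raise ValueError("model spec must end with a sigmoid output layer")
        self.spec = spec
        self.config = config
        init_rng = np.random.default_rng(config.seed)
        self.rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0]
        )
        self.layers: list[_Layer] = []
        shape: tuple[int, ...] = tuple(spec.input_shape)
        for layer_spec, out_shape in zip(spec.layers, infer_shapes(spec)):
            if isinstance(layer_spec, ConvLayerSpec):
                self.layers.append(Conv1D(layer_spec, shape[1], init_rng))
            elif isinstance(layer_spec, EluSpec):
                self.layers.append(Elu(layer_spec))
            elif isinstance(layer_spec, GroupNormSpec):
                self.layers.append(GroupNorm(layer_spec, shape[1], init_rng))
            elif isinstance(layer_spec, MaxPoolSpec):
                self.layers.append(MaxPool1D(layer_spec))
            elif isinstance(layer_spec, DropoutSpec):
                self.layers.append(Dropout(layer_spec, self.rng))
            elif isinstance(layer_spec, FlattenSpec):
                self.layers.append(Flatten())
            elif isinstance(layer_spec, DenseSpec):
                self.layers.append(Dense(layer_spec, shape[0], init_rng))
            elif isinstance(layer_spec, SigmoidSpec):
                pass  # applied analytically; see forward_logits
            else:  # pragma: no cover
                raise TypeError(f"unknown layer spec {layer_spec!r}")
            shape = out_shape

    # ---- forward / loss -------------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x.ravel()

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class-1 probabilities in (0, 1), deterministic (no dropout)."""
        out = [
            sigmoid(self.forward_logits(X[i : i + batch_size], training=False))
            for i in range(0, len(X), batch_size)
        ]
        return np.concatenate(out) if out else np.empty(0)

    def l2_penalty(self) -> float:
        return sum(layer.l2_penalty() for layer in self.layers)

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """Returns (loss, accuracy); loss = BCE + L2 penalty."""
        logits = np.concatenate(
            [self.forward_logits(X[i : i + 256], training=False) for i in range(0, len(X), 256)]
        )
        loss = bce_from_logits(logits, y) + self.l2_penalty()
        acc = float(((logits >= 0.0).astype(int) == y).mean())
        return loss, acc

    # ---- weights --------------------------------------------------------

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_weights(self, weights: Sequence[dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights, strict=True):
            for k in layer.params:
                layer.params[k] = w[k].copy()

    # ---- training -------------------------------------------------------

    def _train_batch(self, xb: np.ndarray, yb: np.ndarray, velocity) -> float:
        logits = self.forward_logits(xb, training=True)
        p = sigmoid(logits)
        loss = bce_from_logits(logits, yb) + self.l2_penalty()
        dy = ((p - yb) / len(yb)).reshape(-1, 1)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        lr, mu = self.config.learning_rate, self.config.momentum
        for layer, vel in zip(self.layers, velocity):
            layer.add_l2_grads()
            for k, g in layer.grads.items():
                vel[k] = mu * vel[k] - lr * g
                layer.params[k] += vel[k]
        return loss

    def fit(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        verbose: bool = False,
    ) -> dict:
        """Train with early stopping; restores the checkpointed best weights.

        Returns a history dict with per-epoch ``train_loss`` / ``val_loss``
        / ``val_accuracy`` plus ``best_epoch`` (1-based), the best monitored
        values, and ``stopped_epoch``.
        """
        if len(X_train) == 0 or len(X_val) == 0:
            raise ValueError("training and validation sets must be non-empty")
        cfg = self.config
        y_train = np.asarray(y_train, dtype=np.float64)
        y_val = np.asarray(y_val, dtype=np.float64)
        velocity = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in self.layers
        ]
        history: dict = {"train_loss": [], "val_loss": [], "val_accuracy": []}
        best_weights = self.get_weights()
        best_metric = -np.inf
        best_epoch = 0
        since_improve = 0
        stopped_epoch = cfg.epochs
        n = len(X_train)
        for epoch in range(1, cfg.epochs + 1):
            order = self.rng.permutation(n)
            batch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                batch_losses.append(self._train_batch(X_train[idx], y_train[idx], velocity))
            val_loss, val_acc = self.evaluate(X_val, y_val)
            history["train_loss"].append(float(np.mean(batch_losses)))
            history["val_loss"].append(val_loss)
            history["val_accuracy"].append(val_acc)
            metric = val_acc if cfg.monitor == "val_accuracy" else -val_loss
            if verbose:  # pragma: no cover
                print(
                    f"epoch {epoch:3d}  train_loss {history['train_loss'][-1]:.4f}"
                    f"  val_loss {val_loss:.4f}  val_acc {val_acc:.4f}"
                )
            if metric > best_metric:
                best_metric = metric
                best_epoch = epoch
                best_weights = self.get_weights()
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= cfg.early_stop_patience:
                    stopped_epoch = epoch
                    break
        self.set_weights(best_weights)
        history["best_epoch"] = best_epoch
        history["best_val_loss"] = history["val_loss"][best_epoch - 1]
        history["best_val_accuracy"] = history["val_accuracy"][best_epoch - 1]
        history["stopped_epoch"] = stopped_epoch
        return history

    # ---- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: weights plus the embedded spec and config (npz)."""
        arrays = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                arrays[f"layer{i}/{k}"] = v
        meta = {
            "spec": self.spec.to_dict(),
            "config": {
                "learning_rate": self.config.learning_rate,
                "momentum": self.config.momentum,
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "early_stop_patience": self.config.early_stop_patience,
                "monitor": self.config.monitor,
                "seed": self.config.seed,
            },
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        net = cls(ModelSpec.from_dict(meta["spec"]), TrainingConfig(**meta["config"]))
        for i, layer in enumerate(net.layers):
            for k in layer.params:
                layer.params[k] = data[f"layer{i}/{k}"].copy()
        return net
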