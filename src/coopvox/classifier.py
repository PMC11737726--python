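"""A compact 1D convolutional network over mel-band energy features.

Architecture: three blocks of Conv1D -> ReLU -> MaxPool1D -> Dropout with
32, 64 and 128 filters, then Flatten -> Dense(ReLU) -> Dense(softmax over
the six call classes). Convolution runs along the frame (time) axis with
mel bands as input channels. Training minimizes categorical cross-entropy
with Adam and early stopping on validation loss; features are standardized
per band using training-split statistics, which are persisted with the
model. Everything is plain numpy, seeded, and reproducible run-to-run on a
single thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synth import CLASS_ORDER

DEFAULT_LABELS: tuple[str, ...] = tuple(c.name for c in CLASS_ORDER)


@dataclass(frozen=True)
class ModelConfig:
    conv_filters: tuple[int, ...] = (32, 64, 128)
    kernel_size: int = 3
    pool_size: int = 2
    dropout_rates: tuple[float, ...] = (0.25, 0.25, 0.5)
    dense_units: int = 64
    n_classes: int = 6
    input_shape: tuple[int, int] = (198, 40)   # (frames, bands)

    def __post_init__(self) -> None:
        if len(self.conv_filters) != len(self.dropout_rates):
            raise ValueError("need one dropout rate per conv block")
        if any(not 0 <= r < 1 for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stop_patience: int = 5
    seed: int = 0


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _Conv1D(_Layer):
    """Valid convolution along time; channels last. Weight layout
    (kernel, in_channels, out_channels)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng) -> None:
        super().__init__()
        self.kernel = kernel
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.params["W"] = rng.normal(0, scale, size=(kernel, c_in, c_out))
        self.params["b"] = np.zeros(c_out)

    def _cols(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        s = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        # (B, T-k+1, C, k) -> (B, T-k+1, k*C)
        return np.ascontiguousarray(s.transpose(0, 1, 3, 2)).reshape(
            x.shape[0], x.shape[1] - k + 1, k * x.shape[2])

    def forward(self, x, train, rng):
        self._x_shape = x.shape
        self._cols_cache = self._cols(x)
        k, c_in, c_out = self.params["W"].shape
        w2 = self.params["W"].reshape(k * c_in, c_out)
        return self._cols_cache @ w2 + self.params["b"]

    def backward(self, dy):
        k, c_in, c_out = self.params["W"].shape
        b, tw, _ = dy.shape
        cols = self._cols_cache.reshape(-1, k * c_in)
        dy2 = dy.reshape(-1, c_out)
        self.grads["W"] = (cols.T @ dy2).reshape(k, c_in, c_out)
        self.grads["b"] = dy2.sum(axis=0)
        dcols = (dy2 @ self.params["W"].reshape(k * c_in, c_out).T
                 ).reshape(b, tw, k, c_in)
        dx = np.zeros(self._x_shape)
        for i in range(k):
            dx[:, i:i + tw, :] += dcols[:, :, i, :]
        return dx


class _ReLU(_Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool1D(_Layer):
    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, train, rng):
        b, t, c = x.shape
        tp = t // self.pool
        self._in_shape = x.shape
        xw = x[:, : tp * self.pool, :].reshape(b, tp, self.pool, c)
        self._argmax = xw.argmax(axis=2)
        return xw.max(axis=2)

    def backward(self, dy):
        b, tp, c = dy.shape
        dx = np.zeros(self._in_shape)
        dxw = dx[:, : tp * self.pool, :].reshape(b, tp, self.pool, c)
        bi, ti, ci = np.ogrid[:b, :tp, :c]
        dxw[bi, ti, self._argmax, ci] = dy
        return dx


class _Dropout(_Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _Flatten(_Layer):
    def forward(self, x, train, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng) -> None:
        super().__init__()
        self.params["W"] = rng.normal(0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class CNN1D:
    """The three-block Conv1D classifier with persisted label order and
    per-band normalization statistics."""

    def __init__(self, config: ModelConfig, layers: list[_Layer],
                 labels: tuple[str, ...]) -> None:
        self.config = config
        self.layers = layers
        self.labels = tuple(labels)
        self.norm_mean: np.ndarray | None = None
        self.norm_std: np.ndarray | None = None
        self.history: dict[str, list[float]] = {}

    # -- forward -----------------------------------------------------------
    def _normalize(self, x: np.ndarray) -> np.ndarray:
        if self.norm_mean is None:
            return x
        return (x - self.norm_mean) / self.norm_std

    def forward(self, x: np.ndarray, train: bool = False, rng=None,
                activation_hook=None) -> np.ndarray:
        """Logits for a batch (B, frames, bands). ``activation_hook(i, a)``
        may transform each layer output (used for simulated quantization)."""
        a = self._normalize(np.asarray(x, dtype=float))
        if activation_hook is not None:
            a = activation_hook(-1, a)
        for i, layer in enumerate(self.layers):
            a = layer.forward(a, train, rng)
            if activation_hook is not None:
                a = activation_hook(i, a)
        return a

    def predict_proba(self, x: np.ndarray, activation_hook=None) -> np.ndarray:
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != tuple(self.config.input_shape):
            raise ValueError(
                f"feature shape {x.shape[1:]} does not match model input "
                f"{tuple(self.config.input_shape)}")
        return _softmax(self.forward(x, train=False,
                                     activation_hook=activation_hook))

    def predict(self, x: np.ndarray, activation_hook=None
                ) -> tuple[np.ndarray, list[str]]:
        probs = self.predict_proba(x, activation_hook=activation_hook)
        idx = probs.argmax(axis=1)
        return probs, [self.labels[i] for i in idx]

    # -- bookkeeping -------------------------------------------------------
    def parameter_count(self) -> int:
        return sum(p.size for layer in self.layers
                   for p in layer.params.values())

    def weight_tensors(self) -> list[tuple[int, str, np.ndarray]]:
        """(layer_index, name, array) for every trainable tensor."""
        return [(i, name, layer.params[name])
                for i, layer in enumerate(self.layers)
                for name in layer.params]

    def copy(self) -> "CNN1D":
        import copy as _copy
        clone = CNN1D(self.config, _copy.deepcopy(self.layers), self.labels)
        clone.norm_mean = None if self.norm_mean is None else self.norm_mean.copy()
        clone.norm_std = None if self.norm_std is None else self.norm_std.copy()
        clone.history = {k: list(v) for k, v in self.history.items()}
        return clone

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"layer{i}_{name}": arr
                  for i, name, arr in self.weight_tensors()}
        if self.norm_mean is not None:
            arrays["norm_mean"] = self.norm_mean
            arrays["norm_std"] = self.norm_std
        meta = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.config.__dict__.items()},
            "labels": list(self.labels),
            "history": self.history,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CNN1D":
        data = np.load(path)
        meta = json.loads(bytes(data["meta_json"]).decode())
        cfg = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in meta["config"].items()}
        model = build_model(ModelConfig(**cfg), labels=tuple(meta["labels"]))
        for i, name, _ in model.weight_tensors():
            model.layers[i].params[name] = data[f"layer{i}_{name}"]
        if "norm_mean" in data:
            model.norm_mean = data["norm_mean"]
            model.norm_std = data["norm_std"]
        model.history = meta["history"]
        return model


def _block_output_frames(config: ModelConfig) -> list[int]:
    t = config.input_shape[0]
    out = []
    for _ in config.conv_filters:
        t = t - config.kernel_size + 1
        t = t // config.pool_size
        out.append(t)
    return out


def minimum_input_frames(config: ModelConfig) -> int:
    """Smallest frame count for which all conv/pool blocks stay nonempty."""
    t = 1
    for _ in config.conv_filters:
        t = t * config.pool_size + config.kernel_size - 1
    return t


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0,
                labels: tuple[str, ...] = DEFAULT_LABELS) -> CNN1D:
    """Assemble the (untrained) network with seeded He initialization."""
    if len(labels) != config.n_classes:
        raise ValueError("label count must equal n_classes")
    frames_out = _block_output_frames(config)
    if frames_out[-1] < 1:
        raise ValueError(
            f"input of {config.input_shape[0]} frames is too short for "
            f"{len(config.conv_filters)} conv/pool blocks; need at least "
            f"{minimum_input_frames(config)} frames")
    rng = np.random.default_rng(seed)
    layers: list[_Layer] = []
    c_in = config.input_shape[1]
    for c_out, rate in zip(config.conv_filters, config.dropout_rates):
        layers += [_Conv1D(c_in, c_out, config.kernel_size, rng), _ReLU(),
                   _MaxPool1D(config.pool_size), _Dropout(rate)]
        c_in = c_out
    layers.append(_Flatten())
    flat = frames_out[-1] * config.conv_filters[-1]
    layers += [_Dense(flat, config.dense_units, rng), _ReLU(),
               _Dense(config.dense_units, config.n_classes, rng)]
    return CNN1D(config, layers, labels)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, model: CNN1D, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {key: np.zeros_like(arr)
                  for key, arr in self._tensors(model).items()}
        self.v = {key: np.zeros_like(arr) for key, arr in self.m.items()}

    @staticmethod
    def _tensors(model: CNN1D) -> dict[str, np.ndarray]:
        return {f"{i}/{name}": arr for i, name, arr in model.weight_tensors()}

    def step(self, model: CNN1D) -> None:
        self.t += 1
        for i, layer in enumerate(model.layers):
            for name in layer.params:
                key = f"{i}/{name}"
                g = layer.grads[name]
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g ** 2
                mhat = self.m[key] / (1 - self.b1 ** self.t)
                vhat = self.v[key] / (1 - self.b2 ** self.t)
                layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _one_hot(y_idx: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y_idx), n_classes))
    out[np.arange(len(y_idx)), y_idx] = 1.0
    return out


def _ce_loss_and_grad(logits: np.ndarray, y_onehot: np.ndarray
                      ) -> tuple[float, np.ndarray]:
    probs = _softmax(logits)
    loss = -np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1))
    return loss, (probs - y_onehot) / len(logits)


def labels_to_indices(labels, label_order: tuple[str, ...]) -> np.ndarray:
    lut = {lab: i for i, lab in enumerate(label_order)}
    try:
        return np.array([lut[getattr(l, "name", l)] for l in labels])
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from None


def train(model: CNN1D, x_train: np.ndarray, y_train, x_val: np.ndarray,
          y_val, tc: TrainConfig = TrainConfig()) -> CNN1D:
    """Train with Adam + early stopping on validation loss.

    ``y_*`` are label names (or VocalClass values) in the model's label
    order. Per-band standardization statistics are computed from the
    training split only and stored on the model; the best-validation-loss
    weights are restored at the end. The history (loss/accuracy per epoch
    for both splits) is recorded on the returned model.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("both train and val splits must be nonempty")
    yi_tr = labels_to_indices(y_train, model.labels)
    yi_va = labels_to_indices(y_val, model.labels)

    # per-band z-scoring from the training split only
    model.norm_mean = x_train.mean(axis=(0, 1))
    std = x_train.std(axis=(0, 1))
    model.norm_std = np.where(std > 1e-8, std, 1.0)

    rng = np.random.default_rng(tc.seed)
    opt = _Adam(model, tc.learning_rate)
    onehot_tr = _one_hot(yi_tr, model.config.n_classes)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_loss, best_state, bad_epochs = np.inf, None, 0

    for _epoch in range(tc.epochs):
        order = rng.permutation(len(x_train))
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, len(order), tc.batch_size):
            sel = order[start:start + tc.batch_size]
            logits = model.forward(x_train[sel], train=True, rng=rng)
            loss, dlogits = _ce_loss_and_grad(logits, onehot_tr[sel])
            grad = dlogits
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            opt.step(model)
            ep_loss += loss * len(sel)
            ep_correct += int((logits.argmax(axis=1) == yi_tr[sel]).sum())
        val_logits = model.forward(x_val, train=False)
        val_loss, _ = _ce_loss_and_grad(val_logits, _one_hot(yi_va, model.config.n_classes))
        history["train_loss"].append(ep_loss / len(order))
        history["train_acc"].append(ep_correct / len(order))
        history["val_loss"].append(float(val_loss))
        history["val_acc"].append(
            float((val_logits.argmax(axis=1) == yi_va).mean()))

        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_state = [{k: v.copy() for k, v in layer.params.items()}
                          for layer in model.layers]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > tc.early_stop_patience:
                break

    if best_state is not None:
        for layer, state in zip(model.layers, best_state):
            layer.params.update(state)
    model.history = history
    return model
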