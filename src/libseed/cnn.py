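"""One-dimensional convolutional network for spectra, in pure NumPy.

Architecture (fixed):

    Conv1d(1 -> 32, kernel 3, stride 1, valid) + BatchNorm + ReLU
    MaxPool(size 2, stride 2)
    Conv1d(32 -> 16, kernel 3, stride 1, valid) + BatchNorm   (no activation)
    Flatten
    Dense(512) + BatchNorm + ReLU + Dropout(0.5)
    Dense(32)  + BatchNorm + ReLU + Dropout(0.2)
    Dense(3)   + ReLU
    Softmax

trained by minimising softmax cross-entropy with Adam (default learning
rate 1e-5, batch size 20, 1000 epochs, weight decay 1e-4 on the conv/dense
weights, Xavier/Glorot-uniform initialisation).  The ReLU in front of the
softmax and the activation-free second convolution are deliberate parts of
the architecture; `final_relu=False` disables the former.

The engine is a small deterministic forward/backward implementation: given
a seed and a fixed BLAS thread count, the loss curve is reproducible
bit for bit.  It is desk-scale by design (hundreds of spectra, thousands of
channels), not a general deep-learning framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# single precision throughout the engine: 2x memory bandwidth, and the
# determinism contract (same seed, same thread count -> bitwise-equal loss
# curve) is unaffected
DTYPE = np.float32
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "CnnTrainConfig",
    "conv_output_length",
    "flatten_size",
    "build_cnn",
    "SpectralCNNClassifier",
    "train_cnn",
    "predict_cnn",
]


def conv_output_length(length: int, kernel: int = 3) -> int:
    return length - kernel + 1


def flatten_size(input_length: int) -> int:
    """Flatten width after conv(3) -> pool(2,2) -> conv(3) with 16 channels:
    16 * (floor((L - 2) / 2) - 2)."""
    return 16 * ((input_length - 2) // 2 - 2)


# ---------------------------------------------------------------- layers

class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train):            # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):                  # pragma: no cover - interface
        raise NotImplementedError


def _xavier(rng, fan_in, fan_out, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class _Conv1d(_Layer):
    def __init__(self, rng, c_in, c_out, k=3):
        super().__init__()
        self.k = k
        self.params = {"W": _xavier(rng, c_in * k, c_out * k, (c_out, c_in, k)),
                       "b": np.zeros(c_out, dtype=DTYPE)}

    def forward(self, x, train):
        self.x_win = sliding_window_view(x, self.k, axis=2)  # (b,c,l_out,k)
        return (np.einsum("bclk,ock->bol", self.x_win, self.params["W"],
                          optimize=True)
                + self.params["b"][None, :, None])

    def backward(self, g):
        self.grads["W"] = np.einsum("bclk,bol->ock", self.x_win, g,
                                    optimize=True)
        self.grads["b"] = g.sum(axis=(0, 2))
        pad = np.pad(g, ((0, 0), (0, 0), (self.k - 1, self.k - 1)))
        return np.einsum("bosk,ock->bcs", sliding_window_view(pad, self.k, 2),
                         self.params["W"][:, :, ::-1], optimize=True)


class _BatchNorm(_Layer):
    """Normalises over batch (and length, for channel-first conv maps)."""

    def __init__(self, n, conv=False, momentum=0.9, eps=1e-5):
        super().__init__()
        self.conv, self.momentum, self.eps = conv, momentum, eps
        self.params = {"gamma": np.ones(n, dtype=DTYPE),
                       "beta": np.zeros(n, dtype=DTYPE)}
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)

    def _shape(self, v):
        return v[None, :, None] if self.conv else v[None, :]

    def forward(self, x, train):
        axes = (0, 2) if self.conv else (0,)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
            self.n_red = x.size // x.shape[1]
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - self._shape(mean)) * self._shape(self.inv_std)
        return self._shape(self.params["gamma"]) * self.xhat \
            + self._shape(self.params["beta"])

    def backward(self, g):
        axes = (0, 2) if self.conv else (0,)
        self.grads["gamma"] = (g * self.xhat).sum(axis=axes)
        self.grads["beta"] = g.sum(axis=axes)
        gmean = g.mean(axis=axes)
        gx_mean = (g * self.xhat).mean(axis=axes)
        return (self._shape(self.params["gamma"] * self.inv_std)
                * (g - self._shape(gmean) - self.xhat * self._shape(gx_mean)))


class _ReLU(_Layer):
    def forward(self, x, train):
        self.mask = x > 0
        return x * self.mask

    def backward(self, g):
        return g * self.mask


class _MaxPool2(_Layer):
    def forward(self, x, train):
        b, c, length = x.shape
        self.in_length = length
        m = length // 2
        xr = x[:, :, :2 * m].reshape(b, c, m, 2)
        self.arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, g):
        b, c, m = g.shape
        out = np.zeros((b, c, m, 2), dtype=g.dtype)
        np.put_along_axis(out, self.arg[..., None], g[..., None], axis=3)
        out = out.reshape(b, c, 2 * m)
        if self.in_length > 2 * m:  # odd tail dropped by floor pooling
            out = np.pad(out, ((0, 0), (0, 0), (0, self.in_length - 2 * m)))
        return out


class _Flatten(_Layer):
    def forward(self, x, train):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self.shape)


class _Dense(_Layer):
    def __init__(self, rng, n_in, n_out):
        super().__init__()
        self.params = {"W": _xavier(rng, n_in, n_out, (n_in, n_out)),
                       "b": np.zeros(n_out, dtype=DTYPE)}

    def forward(self, x, train):
        self.x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] = self.x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T


class _Dropout(_Layer):
    def __init__(self, p, rng):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self.mask = None
            return x
        self.mask = ((self.rng.random(x.shape) >= self.p)
                     .astype(DTYPE) / DTYPE(1.0 - self.p))
        return x * self.mask

    def backward(self, g):
        return g if self.mask is None else g * self.mask


class Network:
    """Plain layer stack with softmax cross-entropy head."""

    def __init__(self, layers, input_length):
        self.layers = layers
        self.input_length = input_length

    def forward(self, x, train=False):
        h = x
        for layer in self.layers:
            h = layer.forward(h, train)
        return h                     # logits, shape (b, 3)

    def predict_proba(self, x):
        logits = self.forward(x, train=False)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grads(self, x, y_idx):
        logits = self.forward(x, train=True)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        n = len(y_idx)
        loss = -np.mean(np.log(p[np.arange(n), y_idx] + 1e-300))
        g = p.copy()
        g[np.arange(n), y_idx] -= 1.0
        g /= n
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return loss

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def n_parameters(self) -> int:
        """Trainable parameters only (batch-norm running stats excluded)."""
        return sum(layer.params[n].size for layer, n in self.parameters())


def build_cnn(input_length: int, rng: np.random.Generator | None = None,
              final_relu: bool = True) -> Network:
    """Assemble the network for spectra of `input_length` channels."""
    if flatten_size(input_length) <= 0 or input_length < 8:
        raise ValueError(
            f"input_length {input_length} too short; need >= 8 so the "
            "conv/pool stack leaves a positive flatten width")
    rng = rng or np.random.default_rng(0)
    flat = flatten_size(input_length)
    layers = [
        _Conv1d(rng, 1, 32), _BatchNorm(32, conv=True), _ReLU(),
        _MaxPool2(),
        _Conv1d(rng, 32, 16), _BatchNorm(16, conv=True),
        _Flatten(),
        _Dense(rng, flat, 512), _BatchNorm(512), _ReLU(), _Dropout(0.5, rng),
        _Dense(rng, 512, 32), _BatchNorm(32), _ReLU(), _Dropout(0.2, rng),
        _Dense(rng, 32, 3),
    ]
    if final_relu:
        layers.append(_ReLU())
    return Network(layers, input_length)


@dataclass
class CnnTrainConfig:
    """Training recipe (defaults are the full-scale profile)."""

    batch_size: int = 20
    learning_rate: float = 1e-5
    epochs: int = 1000
    weight_decay: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs, learning_rate must be positive")


class _Adam:
    def __init__(self, network: Network, cfg: CnnTrainConfig):
        self.cfg = cfg
        self.state = {}
        self.t = 0
        for layer, name in network.parameters():
            self.state[(id(layer), name)] = (
                np.zeros_like(layer.params[name]),
                np.zeros_like(layer.params[name]))

    def step(self, network: Network):
        c = self.cfg
        self.t += 1
        for layer, name in network.parameters():
            g = layer.grads[name]
            if name == "W" and c.weight_decay:
                g = g + c.weight_decay * layer.params[name]
            m, v = self.state[(id(layer), name)]
            m[:] = c.beta1 * m + (1 - c.beta1) * g
            v[:] = c.beta2 * v + (1 - c.beta2) * g * g
            mhat = m / (1 - c.beta1**self.t)
            vhat = v / (1 - c.beta2**self.t)
            layer.params[name] -= c.learning_rate * mhat / (np.sqrt(vhat) + c.eps)


def train_cnn(network: Network, Xcal: np.ndarray, y_idx: np.ndarray,
              config: CnnTrainConfig) -> list[float]:
    """Train in place; returns the per-epoch mean loss curve.

    `y_idx` must already be 0-based class indices.  The last incomplete
    batch of each epoch is kept.  Aborts on a non-finite loss.
    """
    X = np.asarray(Xcal, dtype=DTYPE)[:, None, :]    # (b, 1, L)
    y_idx = np.asarray(y_idx, dtype=int)
    rng = np.random.default_rng(config.seed)
    opt = _Adam(network, config)
    n = len(y_idx)
    loss_curve = []
    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            loss = network.loss_and_grads(X[batch], y_idx[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, "
                    f"batch starting {start}")
            opt.step(network)
            losses.append(loss)
        loss_curve.append(float(np.mean(losses)))
    return loss_curve


def predict_cnn(network: Network, X: np.ndarray,
                classes: np.ndarray | None = None) -> np.ndarray:
    """Argmax class prediction in inference mode (running batch-norm stats,
    dropout off), invariant to batch partitioning."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != network.input_length:
        raise ValueError(
            f"input length {X.shape[1]} != trained length {network.input_length}")
    idx = network.predict_proba(X.astype(DTYPE)[:, None, :]).argmax(axis=1)
    if classes is None:
        classes = np.array([1, 2, 3])
    return classes[idx]


class SpectralCNNClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper tying the network, recipe and label coding
    together.  Labels may be any sortable values (typically 1/2/3); they are
    mapped to 0-based indices internally and back on predict."""

    def __init__(self, epochs: int = 1000, batch_size: int = 20,
                 learning_rate: float = 1e-5, weight_decay: float = 1e-4,
                 final_relu: bool = True, shuffle: bool = True,
                 random_state: int = 0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.final_relu = final_relu
        self.shuffle = shuffle
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        self.classes_ = np.unique(y)
        if self.classes_.size > 3:
            raise ValueError("network head has 3 outputs")
        y_idx = np.searchsorted(self.classes_, y)
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        self.network_ = build_cnn(X.shape[1], rng=rng,
                                  final_relu=self.final_relu)
        cfg = CnnTrainConfig(batch_size=self.batch_size,
                             learning_rate=self.learning_rate,
                             epochs=self.epochs,
                             weight_decay=self.weight_decay,
                             shuffle=self.shuffle,
                             seed=self.random_state + 1)
        self.loss_curve_ = train_cnn(self.network_, X, y_idx, cfg)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        return predict_cnn(self.network_, X, classes=self.classes_)

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        return self.network_.predict_proba(X[:, None, :])
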