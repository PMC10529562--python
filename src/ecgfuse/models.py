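"""Reference classifiers for the unified beat dataset.

Two architectures are provided: a 5-layer fully connected network
(input batch-standardization, four hidden layers of 256 rectified
units with 30% dropout, and a 16-way softmax output) and a 12-layer
1-D residual network (three residual blocks of channel widths 64, 128,
128 whose convolutions use kernel lengths 8, 5 and 3, a 1x1
down-sampling convolution after each of the first two blocks, global
average pooling, and a fully connected softmax head).  Training uses
Adam on the cross-entropy loss.

The layers, backpropagation and optimizer are implemented directly on
numpy arrays; all randomness (initialization, shuffling, dropout) is
driven by explicit seeds, so training runs are bit-reproducible on a
single thread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TrainingDivergedError
from .preprocessing import BeatDataset

# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Layer:
    """Minimal layer protocol: forward caches, backward returns dx."""

    has_weights = False

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self):
        """Yield (param_array, grad_array) pairs, updated in place."""
        return ()


class Dense(Layer):
    has_weights = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization suits the rectifier nonlinearity
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def parameters(self):
        yield self.W, self.dW
        yield self.b, self.db


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, p: float, net: "Network"):
        if not (0.0 <= p < 1.0):
            raise ConfigurationError(f"dropout probability {p} outside [0, 1)")
        self.p = p
        self._net = net

    def forward(self, x, training):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self._net.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Batch normalization over features (2-D input) or channels (3-D)."""

    has_weights = False  # affine scale/shift carry weights but no kernel

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1)

    def forward(self, x, training):
        axes, shp = self._axes(x), self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shp)) * self._inv_std.reshape(shp)
        return self.gamma.reshape(shp) * self._xhat + self.beta.reshape(shp)

    def backward(self, grad):
        axes, shp = self._axes(grad), self._shape(grad)
        n = grad.size // grad.shape[1] if grad.ndim == 3 else grad.shape[0]
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        gxhat = grad * self.gamma.reshape(shp)
        return (
            self._inv_std.reshape(shp)
            / n
            * (
                n * gxhat
                - gxhat.sum(axis=axes).reshape(shp)
                - self._xhat * (gxhat * self._xhat).sum(axis=axes).reshape(shp)
            )
        )

    def parameters(self):
        yield self.gamma, self.dgamma
        yield self.beta, self.dbeta


class Conv1d(Layer):
    """1-D convolution with 'same'-style padding, via windowed matmul."""

    has_weights = True

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1):
        self.k, self.stride = kernel, stride
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = rng.standard_normal((out_ch, in_ch, kernel)) * np.sqrt(
            2.0 / (in_ch * kernel)
        )
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        B, C, Lin = x.shape
        Lout = -(-Lin // self.stride)  # ceil
        pad = max((Lout - 1) * self.stride + self.k - Lin, 0)
        pl, pr = pad // 2, pad - pad // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        s0, s1, s2 = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp,
            shape=(B, C, Lout, self.k),
            strides=(s0, s1, s2 * self.stride, s2),
            writeable=False,
        )
        cols = win.transpose(0, 2, 1, 3).reshape(B, Lout, C * self.k)
        y = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        self._cols, self._pl, self._Lin, self._Lp = cols, pl, Lin, xp.shape[2]
        return y.transpose(0, 2, 1)

    def backward(self, grad):
        B, O, Lout = grad.shape
        g = grad.transpose(0, 2, 1)  # (B, Lout, O)
        self.dW[...] = np.einsum("blo,blk->ok", g, self._cols).reshape(self.W.shape)
        self.db[...] = grad.sum(axis=(0, 2))
        dcols = (g @ self.W.reshape(O, -1)).reshape(B, Lout, self.in_ch, self.k)
        dxp = np.zeros((B, self.in_ch, self._Lp))
        for j in range(self.k):
            dxp[:, :, j : j + self.stride * Lout : self.stride] += dcols[
                :, :, :, j
            ].transpose(0, 2, 1)
        end = self._pl + self._Lin
        return dxp[:, :, self._pl : end]

    def parameters(self):
        yield self.W, self.dW
        yield self.b, self.db


class GlobalAvgPool1d(Layer):
    def forward(self, x, training):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._L, axis=2) / self._L


class AddChannelDim(Layer):
    """(B, L) -> (B, 1, L) adapter between beat matrices and convolutions."""

    def forward(self, x, training):
        return x[:, None, :]

    def backward(self, grad):
        return grad[:, 0, :]


class _Path:
    """A plain sequence of layers used inside residual blocks."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()


class ResidualBlock(Layer):
    """conv(k1)-BN-ReLU, conv(k2)-BN-ReLU, conv(k3)-BN, plus shortcut,
    then a rectifier on the sum.  The shortcut is the identity when the
    channel counts agree and a 1x1 convolution + BN otherwise."""

    has_weights = True

    def __init__(self, in_ch, out_ch, kernels, rng):
        k1, k2, k3 = kernels
        self.main = _Path([
            Conv1d(in_ch, out_ch, k1, rng), BatchNorm(out_ch), ReLU(),
            Conv1d(out_ch, out_ch, k2, rng), BatchNorm(out_ch), ReLU(),
            Conv1d(out_ch, out_ch, k3, rng), BatchNorm(out_ch),
        ])
        if in_ch != out_ch:
            self.shortcut = _Path([Conv1d(in_ch, out_ch, 1, rng), BatchNorm(out_ch)])
        else:
            self.shortcut = None
        self.out_relu = ReLU()

    def forward(self, x, training):
        h = self.main.forward(x, training)
        s = x if self.shortcut is None else self.shortcut.forward(x, training)
        return self.out_relu.forward(h + s, training)

    def backward(self, grad):
        g = self.out_relu.backward(grad)
        dx = self.main.backward(g)
        dx = dx + (g if self.shortcut is None else self.shortcut.backward(g))
        return dx

    def parameters(self):
        yield from self.main.parameters()
        if self.shortcut is not None:
            yield from self.shortcut.parameters()

    @property
    def n_weighted(self) -> int:
        """Convolutions on the main path (shortcut projections are not
        counted, following the usual depth-counting convention)."""
        return 3


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------


class Network:
    """A feed-forward stack ending in a softmax over class logits."""

    def __init__(self, layers, n_classes: int, seed: int = 0, name: str = "net"):
        self.layers = layers
        self.n_classes = n_classes
        self.rng = np.random.default_rng(seed)
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()

    def predict_proba(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        out = []
        for i in range(0, len(X), batch_size):
            logits = self.forward(X[i : i + batch_size], training=False)
            out.append(_softmax(logits))
        return np.concatenate(out) if out else np.empty((0, self.n_classes))

    def predict(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        return self.predict_proba(X, batch_size).argmax(axis=1)

    @property
    def weighted_layers(self) -> int:
        """Kernel-carrying depth: dense + convolutional layers, with
        residual shortcut projections excluded by convention."""
        n = 0
        for layer in self.layers:
            if isinstance(layer, ResidualBlock):
                n += layer.n_weighted
            elif isinstance(layer, (Dense, Conv1d)):
                n += 1
        return n

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p, _ in self.parameters())


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# architecture specs + builders
# ---------------------------------------------------------------------------


@dataclass
class FcNetworkSpec:
    """The 5-layer fully connected classifier (4 hidden + output)."""

    input_units: int = 260
    hidden_units: int = 256
    n_hidden: int = 4
    dropout: float = 0.30
    n_classes: int = 16
    input_batchnorm: bool = True

    def __post_init__(self):
        if self.input_units < 1 or self.hidden_units < 1 or self.n_hidden < 1:
            raise ConfigurationError("layer sizes must be positive")
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")

    @property
    def weighted_layers(self) -> int:
        return self.n_hidden + 1


@dataclass
class ResNetSpec:
    """The 12-layer 1-D residual classifier: 3 blocks x 3 convolutions
    + 2 down-sampling 1x1 convolutions + the fully connected head."""

    input_length: int = 260
    channels: tuple[int, int, int] = (64, 128, 128)
    kernels: tuple[int, int, int] = (8, 5, 3)
    downsample_stride: int = 2
    n_classes: int = 16

    def __post_init__(self):
        if len(self.channels) != 3 or len(self.kernels) != 3:
            raise ConfigurationError("expected 3 residual blocks and 3 kernel sizes")
        if self.input_length < 4 * self.downsample_stride:
            raise ConfigurationError(
                "input too short for two down-sampling stages"
            )

    @property
    def weighted_layers(self) -> int:
        return 3 * len(self.channels) + 2 + 1


def build_fc(spec: FcNetworkSpec = FcNetworkSpec(), seed: int = 0) -> Network:
    """Untrained 5-layer fully connected network per the spec."""
    rng = np.random.default_rng(seed)
    net = Network([], n_classes=spec.n_classes, seed=seed, name="fc5")
    layers: list[Layer] = []
    if spec.input_batchnorm:
        layers.append(BatchNorm(spec.input_units))
    n_in = spec.input_units
    for _ in range(spec.n_hidden):
        layers += [Dense(n_in, spec.hidden_units, rng), ReLU(),
                   Dropout(spec.dropout, net)]
        n_in = spec.hidden_units
    layers.append(Dense(n_in, spec.n_classes, rng))
    net.layers = layers
    return net


def build_resnet(spec: ResNetSpec = ResNetSpec(), seed: int = 0) -> Network:
    """Untrained 12-layer 1-D residual network per the spec."""
    rng = np.random.default_rng(seed)
    c1, c2, c3 = spec.channels
    layers: list[Layer] = [AddChannelDim()]
    layers.append(ResidualBlock(1, c1, spec.kernels, rng))
    layers += [Conv1d(c1, c1, 1, rng, stride=spec.downsample_stride),
               BatchNorm(c1), ReLU()]
    layers.append(ResidualBlock(c1, c2, spec.kernels, rng))
    layers += [Conv1d(c2, c2, 1, rng, stride=spec.downsample_stride),
               BatchNorm(c2), ReLU()]
    layers.append(ResidualBlock(c2, c3, spec.kernels, rng))
    layers += [GlobalAvgPool1d(), Dense(c3, spec.n_classes, rng)]
    return Network(layers, n_classes=spec.n_classes, seed=seed, name="resnet12")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    learning_rate: float = 0.001
    max_epochs: int = 200
    batch_size: int = 300
    validation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ConfigurationError("validation_fraction must be in [0, 1)")


class Adam:
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the logits."""
    p = _softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), y] + eps))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def train(
    model: Network,
    train_set: BeatDataset,
    config: TrainConfig = TrainConfig(),
) -> tuple[Network, pd.DataFrame]:
    """Fit a network with Adam on cross-entropy; returns per-epoch history.

    Fully seeded: the shuffle order, validation carve-out and dropout
    masks all derive from ``config.seed``.
    """
    X = np.asarray(train_set.A, dtype=np.float64)
    y = np.asarray(train_set.labels)
    if y.min() < 0 or y.max() >= model.n_classes:
        raise ConfigurationError(
            f"labels span [{y.min()}, {y.max()}] but the model has "
            f"{model.n_classes} classes"
        )
    rng = np.random.default_rng(config.seed)
    model.rng = np.random.default_rng(config.seed + 1)  # dropout stream

    if config.validation_fraction > 0:
        order = rng.permutation(len(X))
        n_val = max(1, int(round(config.validation_fraction * len(X))))
        val_idx, fit_idx = order[:n_val], order[n_val:]
        X_val, y_val = X[val_idx], y[val_idx]
        X_fit, y_fit = X[fit_idx], y[fit_idx]
    else:
        X_val = y_val = None
        X_fit, y_fit = X, y

    batch = int(min(config.batch_size, len(X_fit)))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rows = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X_fit))
        losses, n_correct = [], 0
        for i in range(0, len(order), batch):
            idx = order[i : i + batch]
            logits = model.forward(X_fit[idx], training=True)
            loss, dlogits = cross_entropy(logits, y_fit[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {i // batch}"
                )
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            n_correct += int((logits.argmax(axis=1) == y_fit[idx]).sum())
        row = {
            "epoch": epoch,
            "loss": float(np.sum(losses) / len(X_fit)),
            "accuracy": n_correct / len(X_fit),
        }
        if X_val is not None:
            logits = model.forward(X_val, training=False)
            val_loss, _ = cross_entropy(logits, y_val)
            row["val_loss"] = float(val_loss)
            row["val_accuracy"] = float((logits.argmax(axis=1) == y_val).mean())
        rows.append(row)
    return model, pd.DataFrame(rows)


def fc_parameter_count(spec: FcNetworkSpec) -> int:
    """Closed-form weight+bias count of the fully connected stack
    (batch-normalization scale/shift excluded)."""
    L, H, K = spec.input_units, spec.hidden_units, spec.n_classes
    return (L * H + H) + (spec.n_hidden - 1) * (H * H + H) + (H * K + K)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: Network, spec, path) -> None:
    """Architecture manifest (JSON) + weights (.npz) under a directory."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, (p, _) in enumerate(model.parameters()):
        arrays[f"p{i}"] = p
    # running batch-norm statistics are state, not parameters
    bn_state = {}
    for i, layer in enumerate(_walk_layers(model.layers)):
        if isinstance(layer, BatchNorm):
            bn_state[f"bn{i}_mean"] = layer.running_mean
            bn_state[f"bn{i}_var"] = layer.running_var
    np.savez(d / "weights.npz", **arrays, **bn_state)
    manifest = {
        "arch": model.name,
        "n_classes": model.n_classes,
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_model(path) -> Network:
    import json
    from pathlib import Path

    d = Path(path)
    manifest = json.loads((d / "manifest.json").read_text())
    spec_kw = manifest["spec"]
    if manifest["arch"] == "fc5":
        model = build_fc(FcNetworkSpec(**spec_kw))
    elif manifest["arch"] == "resnet12":
        spec_kw = {k: (tuple(v) if isinstance(v, list) else v)
                   for k, v in spec_kw.items()}
        model = build_resnet(ResNetSpec(**spec_kw))
    else:
        raise ConfigurationError(f"unknown architecture {manifest['arch']!r}")
    data = np.load(d / "weights.npz")
    for i, (p, _) in enumerate(model.parameters()):
        p[...] = data[f"p{i}"]
    for i, layer in enumerate(_walk_layers(model.layers)):
        if isinstance(layer, BatchNorm):
            layer.running_mean = data[f"bn{i}_mean"]
            layer.running_var = data[f"bn{i}_var"]
    return model


def _walk_layers(layers):
    for layer in layers:
        if isinstance(layer, ResidualBlock):
            yield from _walk_layers(layer.main.layers)
            if layer.shortcut is not None:
                yield from _walk_layers(layer.shortcut.layers)
        else:
            yield layer
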