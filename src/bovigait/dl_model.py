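"""Sequence classifier over per-frame indicator series: CNN + BiLSTM.

The network consumes a fixed-length ``T x 5`` matrix per passage (both
spine ratios, the normalized head height and the two leg distances,
resampled to ``T`` uniform time points) and emits a 7-class softmax over
the lameness grades.  The stack is three 1-D convolutions of rising
width (kernel 3, ReLU), a sequence-returning bidirectional LSTM, a
summarizing bidirectional LSTM and a dense softmax head, trained with
categorical cross-entropy and Adam.

The network is implemented directly on numpy — layers, hand-derived
backpropagation and the Adam update live in this module and are
validated against finite-difference gradients in the test suite.  All
randomness (initialization, batching, augmentation, dropout) flows from
explicit seeds, so training is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .indicators import CHANNELS, IndicatorSeries

logger = logging.getLogger("bovigait")

__all__ = [
    "SequenceSample",
    "NetConfig",
    "AugmentParams",
    "DLModel",
    "build_sequence",
    "augment",
    "train_cnn_bilstm",
    "predict_proba",
    "predict_grade",
    "save_dl_model",
    "load_dl_model",
]


# ---------------------------------------------------------------------------
# Sequence construction and augmentation
# ---------------------------------------------------------------------------


@dataclass
class SequenceSample:
    """One passage as a ``T x C`` matrix (C = 5 indicator channels)."""

    matrix: np.ndarray
    label: int | None = None  # grade 1..7
    passage_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("sequence matrix must be T x C")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("sequence matrix must be finite after preprocessing")


def build_sequence(series: IndicatorSeries, T: int = 120) -> SequenceSample:
    """Resample each indicator channel onto ``T`` uniform time points.

    Invalid frames are filled by linear interpolation against frame index
    (constant at the ends); a channel with fewer than two valid frames is
    filled with its single value, or zeros, with a warning.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    t = series.frame_index.astype(float)
    xs = np.linspace(t[0], t[-1], T)
    mat = np.zeros((T, len(CHANNELS)))
    for j, name in enumerate(CHANNELS):
        vals = series.values[name]
        ok = series.valid[name] & np.isfinite(vals)
        if ok.sum() >= 2:
            mat[:, j] = np.interp(xs, t[ok], vals[ok])
        elif ok.sum() == 1:
            logger.warning("channel %s has a single valid frame; filled constant", name)
            mat[:, j] = float(vals[ok][0])
        else:
            logger.warning("channel %s has no valid frames; filled with zeros", name)
    return SequenceSample(matrix=mat, label=None, passage_id=series.passage_id)


@dataclass(frozen=True)
class AugmentParams:
    """Time-series augmentation: Gaussian jitter, optional moving-average
    smoothing (odd window; <=1 disables), and random time-point dropout
    with linear re-interpolation."""

    noise_sigma: float = 0.01
    smooth_window: int = 0
    dropout_frac: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_frac < 1.0:
            raise ValueError("dropout_frac must be in [0, 1)")


def augment(sample: SequenceSample, params: AugmentParams, seed: int) -> SequenceSample:
    """Jitter, smooth and drop-reinterpolate a sample; label unchanged."""
    rng = np.random.default_rng(seed)
    mat = sample.matrix.copy()
    T = mat.shape[0]
    if params.noise_sigma > 0:
        mat = mat + rng.normal(0.0, params.noise_sigma, size=mat.shape)
    if params.smooth_window > 1:
        w = params.smooth_window
        if w % 2 == 0:
            raise ValueError("smooth_window must be odd")
        pad = w // 2
        kern = np.ones(w) / w
        for j in range(mat.shape[1]):
            mat[:, j] = np.convolve(np.pad(mat[:, j], pad, mode="reflect"), kern, "valid")
    n_drop = int(np.floor(params.dropout_frac * T))
    if n_drop > 0:
        drop = rng.choice(T, size=n_drop, replace=False)
        keep = np.setdiff1d(np.arange(T), drop)
        for j in range(mat.shape[1]):
            mat[drop, j] = np.interp(drop.astype(float), keep.astype(float), mat[keep, j])
    return SequenceSample(matrix=mat, label=sample.label, passage_id=sample.passage_id)


# ---------------------------------------------------------------------------
# Layers (numpy, hand-derived gradients)
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv1DRelu:
    """Same-padded 1-D convolution + ReLU over (B, T, Cin) input."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng, dtype=np.float32):
        self.k, self.c_in, self.c_out = kernel_size, c_in, c_out
        self.W = _glorot(rng, (kernel_size * c_in, c_out), kernel_size * c_in, c_out, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._cache = None

    def describe(self) -> dict:
        return {"type": "conv1d", "filters": self.c_out, "kernel_size": self.k,
                "activation": "relu"}

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def _patches(self, X: np.ndarray) -> np.ndarray:
        B, T, C = X.shape
        pad = self.k // 2
        Xp = np.pad(X, ((0, 0), (pad, pad), (0, 0)))
        return np.concatenate([Xp[:, i : i + T] for i in range(self.k)], axis=2)

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        P = self._patches(X)
        Y = P @ self.W + self.b
        np.maximum(Y, 0.0, out=Y)
        self._cache = (P, Y > 0, X.shape)
        return Y

    def backward(self, dY: np.ndarray):
        P, mask, xshape = self._cache
        dY = dY * mask
        B, T, _ = xshape
        dW = P.reshape(B * T, -1).T @ dY.reshape(B * T, -1)
        db = dY.sum(axis=(0, 1))
        dP = dY @ self.W.T
        pad = self.k // 2
        dXp = np.zeros((B, T + 2 * pad, self.c_in), dtype=dY.dtype)
        for i in range(self.k):
            dXp[:, i : i + T] += dP[:, :, i * self.c_in : (i + 1) * self.c_in]
        dX = dXp[:, pad : pad + T]
        return dX, [dW, db]


class _LSTMDirection:
    """One direction of an LSTM; gate order i, f, g, o; forget bias 1."""

    def __init__(self, c_in: int, units: int, rng, dtype=np.float32):
        H = units
        self.c_in, self.units = c_in, H
        self.Wx = _glorot(rng, (c_in, 4 * H), c_in, 4 * H, dtype)
        self.Wh = _glorot(rng, (H, 4 * H), H, 4 * H, dtype)
        self.b = np.zeros(4 * H, dtype=dtype)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self._cache = None

    def params(self):
        return [("Wx", self.Wx), ("Wh", self.Wh), ("b", self.b)]

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        H = self.units
        dtype = self.Wx.dtype
        Zx = X @ self.Wx + self.b  # (B, T, 4H), input projections for all steps
        Hs = np.zeros((B, T, H), dtype=dtype)
        gates = np.zeros((B, T, 4 * H), dtype=dtype)
        Cs = np.zeros((B, T, H), dtype=dtype)
        h = np.zeros((B, H), dtype=dtype)
        c = np.zeros((B, H), dtype=dtype)
        for ti in range(T):
            z = Zx[:, ti] + h @ self.Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[:, ti, :H] = i
            gates[:, ti, H : 2 * H] = f
            gates[:, ti, 2 * H : 3 * H] = g
            gates[:, ti, 3 * H :] = o
            Cs[:, ti] = c
            Hs[:, ti] = h
        self._cache = (X, Hs, Cs, gates)
        return Hs

    def backward(self, dHs: np.ndarray):
        X, Hs, Cs, gates = self._cache
        B, T, _ = X.shape
        H = self.units
        dtype = self.Wx.dtype
        dZ = np.zeros((B, T, 4 * H), dtype=dtype)
        dh_next = np.zeros((B, H), dtype=dtype)
        dc_next = np.zeros((B, H), dtype=dtype)
        for ti in range(T - 1, -1, -1):
            i = gates[:, ti, :H]
            f = gates[:, ti, H : 2 * H]
            g = gates[:, ti, 2 * H : 3 * H]
            o = gates[:, ti, 3 * H :]
            c = Cs[:, ti]
            c_prev = Cs[:, ti - 1] if ti > 0 else np.zeros_like(c)
            tc = np.tanh(c)
            dh = dHs[:, ti] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dzo = dh * tc * o * (1.0 - o)
            dzi = dc * g * i * (1.0 - i)
            dzf = dc * c_prev * f * (1.0 - f)
            dzg = dc * i * (1.0 - g * g)
            dz = np.concatenate([dzi, dzf, dzg, dzo], axis=1)
            dZ[:, ti] = dz
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        H_prev = np.concatenate([np.zeros((B, 1, H), dtype=dtype), Hs[:, :-1]], axis=1)
        flatZ = dZ.reshape(B * T, 4 * H)
        dWx = X.reshape(B * T, -1).T @ flatZ
        dWh = H_prev.reshape(B * T, H).T @ flatZ
        db = flatZ.sum(axis=0)
        dX = dZ @ self.Wx.T
        return dX, [dWx, dWh, db]


class BiLSTM:
    """Bidirectional LSTM; concatenates the two directions' features."""

    def __init__(self, c_in: int, units: int, return_sequences: bool, rng, dtype=np.float32):
        self.units = units
        self.return_sequences = return_sequences
        self.fwd = _LSTMDirection(c_in, units, rng, dtype)
        self.bwd = _LSTMDirection(c_in, units, rng, dtype)

    def describe(self) -> dict:
        return {"type": "bilstm", "units": self.units,
                "return_sequences": self.return_sequences}

    def params(self):
        return [(f"fwd_{n}", p) for n, p in self.fwd.params()] + [
            (f"bwd_{n}", p) for n, p in self.bwd.params()
        ]

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        Hf = self.fwd.forward(X)
        Hb = self.bwd.forward(X[:, ::-1])
        if self.return_sequences:
            return np.concatenate([Hf, Hb[:, ::-1]], axis=2)
        return np.concatenate([Hf[:, -1], Hb[:, -1]], axis=1)

    def backward(self, dY: np.ndarray):
        H = self.units
        if self.return_sequences:
            dHf = dY[:, :, :H]
            dHb = dY[:, :, H:][:, ::-1]
        else:
            B = dY.shape[0]
            T = self.fwd._cache[1].shape[1]
            dtype = dY.dtype
            dHf = np.zeros((B, T, H), dtype=dtype)
            dHb = np.zeros((B, T, H), dtype=dtype)
            dHf[:, -1] = dY[:, :H]
            dHb[:, -1] = dY[:, H:]
        dXf, gf = self.fwd.backward(np.ascontiguousarray(dHf))
        dXb, gb = self.bwd.backward(np.ascontiguousarray(dHb))
        return dXf + dXb[:, ::-1], gf + gb


class Dropout:
    """Inverted dropout on the time-feature tensor (train time only)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def describe(self) -> dict:
        return {"type": "dropout", "rate": self.rate}

    def params(self):
        return []

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return X
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(X.shape) < keep).astype(X.dtype) / keep
        return X * self._mask

    def backward(self, dY: np.ndarray):
        if self._mask is None:
            return dY, []
        return dY * self._mask, []


class DenseSoftmax:
    """Dense layer producing class logits; softmax applied in the loss."""

    def __init__(self, c_in: int, n_classes: int, rng, dtype=np.float32):
        self.n_classes = n_classes
        self.W = _glorot(rng, (c_in, n_classes), c_in, n_classes, dtype)
        self.b = np.zeros(n_classes, dtype=dtype)
        self._cache = None

    def describe(self) -> dict:
        return {"type": "dense", "units": self.n_classes, "activation": "softmax"}

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        self._cache = X
        return X @ self.W + self.b

    def backward(self, dY: np.ndarray):
        X = self._cache
        return dY @ self.W.T, [X.T @ dY, dY.sum(axis=0)]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Network:
    """An ordered layer stack with categorical cross-entropy loss."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        out = X
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def loss_and_grads(self, X: np.ndarray, Y_onehot: np.ndarray):
        """Mean cross-entropy and gradients for every parameter."""
        logits = self.forward(X, train=True)
        P = _softmax(logits.astype(np.float64))
        B = X.shape[0]
        eps = 1e-12
        loss = float(-np.mean(np.log(np.sum(P * Y_onehot, axis=1) + eps)))
        dY = ((P - Y_onehot) / B).astype(logits.dtype)
        grads: list[list[np.ndarray]] = []
        for layer in reversed(self.layers):
            dY, g = layer.backward(dY)
            grads.append(g)
        grads.reverse()
        return loss, grads

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(p for _, p in layer.params())
        return out

    def flat_grads(self, grads: list[list[np.ndarray]]) -> list[np.ndarray]:
        out = []
        for g in grads:
            out.extend(g)
        return out


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Public model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetConfig:
    """Architecture and optimization settings.

    The convolutional widths must rise within [128, 320] and the kernel
    size is fixed at 3; the first recurrent layer returns sequences with
    256 units per direction, the second summarizes with 512.
    """

    conv_filters: tuple[int, ...] = (128, 192, 320)
    kernel_size: int = 3
    lstm1_units: int = 256
    lstm2_units: int = 512
    n_classes: int = 7
    learning_rate: float = 1e-3
    dropout: float = 0.1
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size != 3:
            raise ValueError("kernel_size is fixed at 3")
        f = self.conv_filters
        if not f or list(f) != sorted(f) or min(f) < 128 or max(f) > 320:
            raise ValueError("conv_filters must rise within [128, 320]")
        if self.n_classes != 7:
            raise ValueError("the classifier head has 7 grades")


GRADES = tuple(range(1, 8))


@dataclass
class DLModel:
    config: NetConfig
    network: _Network
    loss_trace: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    # per-channel standardization fitted on the training set
    channel_mean: np.ndarray | None = None
    channel_std: np.ndarray | None = None

    def architecture(self) -> list[dict]:
        return [layer.describe() for layer in self.network.layers]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if self.channel_mean is None:
            return X
        return (X - self.channel_mean.astype(X.dtype)) / self.channel_std.astype(X.dtype)


def _build_network(config: NetConfig, n_channels: int, rng, dtype=np.float32) -> _Network:
    layers: list = []
    c = n_channels
    for f in config.conv_filters:
        layers.append(Conv1DRelu(c, f, config.kernel_size, rng, dtype))
        c = f
    layers.append(BiLSTM(c, config.lstm1_units, return_sequences=True, rng=rng, dtype=dtype))
    if config.dropout > 0:
        layers.append(Dropout(config.dropout, rng))
    layers.append(BiLSTM(2 * config.lstm1_units, config.lstm2_units, return_sequences=False,
                         rng=rng, dtype=dtype))
    layers.append(DenseSoftmax(2 * config.lstm2_units, config.n_classes, rng, dtype))
    return _Network(layers)


def _stack(samples: list[SequenceSample], dtype=np.float32):
    X = np.stack([s.matrix for s in samples]).astype(dtype)
    labels = [s.label for s in samples]
    if any(l is None for l in labels):
        raise ValueError("all training samples need a grade label")
    Y = np.zeros((len(samples), len(GRADES)))
    for i, l in enumerate(labels):
        Y[i, int(l) - 1] = 1.0
    return X, Y


def train_cnn_bilstm(samples: list[SequenceSample], config: NetConfig | None = None) -> DLModel:
    """Train the sequence classifier; deterministic given ``config.seed``."""
    config = config or NetConfig()
    X, Y = _stack(samples)
    if np.unique(Y.argmax(axis=1)).size < 2:
        raise ValueError("need at least 2 classes to train")
    rng = np.random.default_rng(config.seed)
    net = _build_network(config, X.shape[2], rng)
    opt = _Adam(net.parameters(), config.learning_rate)
    n = X.shape[0]
    # per-channel standardization keeps the optimization well conditioned
    mean = X.mean(axis=(0, 1), dtype=np.float64)
    std = X.std(axis=(0, 1), dtype=np.float64)
    std[std < 1e-8] = 1.0
    model = DLModel(config=config, network=net, channel_mean=mean, channel_std=std)
    X = model.standardize(X)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = net.loss_and_grads(X[idx], Y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // config.batch_size}; "
                    f"lr={config.learning_rate}"
                )
            opt.step(net.flat_grads(grads))
            epoch_loss += loss * len(idx)
        preds = _softmax(net.forward(X)).argmax(axis=1)
        acc = float(np.mean(preds == Y.argmax(axis=1)))
        model.loss_trace.append(epoch_loss / n)
        model.train_accuracy.append(acc)
        logger.debug("epoch %d: loss %.4f train-acc %.3f", epoch, epoch_loss / n, acc)
    return model


def predict_proba(model: DLModel, sample: SequenceSample) -> np.ndarray:
    """7-class probability vector for one sample (sums to 1)."""
    X = model.standardize(sample.matrix[None].astype(np.float32))
    return _softmax(model.network.forward(X).astype(np.float64))[0]


def predict_grade(model: DLModel, sample: SequenceSample) -> int:
    return int(GRADES[int(np.argmax(predict_proba(model, sample)))])


# ---------------------------------------------------------------------------
# Serialization: one .npz holding config + weights
# ---------------------------------------------------------------------------


def save_dl_model(model: DLModel, path) -> None:
    arrays = {}
    for li, layer in enumerate(model.network.layers):
        for name, p in layer.params():
            arrays[f"layer{li}_{name}"] = p
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(model.config).items()}
    meta = {"config": cfg, "loss_trace": model.loss_trace,
            "train_accuracy": model.train_accuracy,
            "n_channels": model.network.layers[0].c_in}
    if model.channel_mean is not None:
        arrays["__channel_mean__"] = model.channel_mean
        arrays["__channel_std__"] = model.channel_std
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_dl_model(path) -> DLModel:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg = dict(meta["config"])
    cfg["conv_filters"] = tuple(cfg["conv_filters"])
    config = NetConfig(**cfg)
    rng = np.random.default_rng(config.seed)
    net = _build_network(config, int(meta["n_channels"]), rng)
    for li, layer in enumerate(net.layers):
        for name, p in layer.params():
            p[...] = data[f"layer{li}_{name}"]
    mean = data["__channel_mean__"] if "__channel_mean__" in data else None
    std = data["__channel_std__"] if "__channel_std__" in data else None
    return DLModel(config=config, network=net,
                   loss_trace=list(meta["loss_trace"]),
                   train_accuracy=list(meta["train_accuracy"]),
                   channel_mean=mean, channel_std=std)
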