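"""Temporal convolutional network for per-timestep gait-event probabilities.

Architecture: a stack of ``n_blocks`` residual blocks with exponentially
increasing dilation (block m has dilation ``dilation_base**(m-1)``), each
block being two sequences of [dilated conv -> batch norm -> ReLU -> dropout]
plus a residual path (identity, or a kernel-1 convolution when channel counts
differ), an elementwise sum and a final ReLU. A per-timestep dense layer and
softmax turn the last block's 64 feature maps into class probabilities over
[null, IC left, FC left, IC right, FC right]. With the defaults (6 blocks,
64 filters, kernel 3) the maximum dilation is 32 and the receptive field is
1 + sum_m 2*(kernel-1)*dilation_m = 253 samples (2.53 s at 100 Hz).

Convolutions are non-causal with zero same-length padding: the network is
meant for offline analysis of recorded walking bouts, where looking a second
ahead of a sample is legitimate and halves the effective latency-induced
bias compared to a causal stack.

The implementation is pure NumPy (forward, backward, Adam); training is
deterministic given the seed. Inputs are standardized per channel with
statistics estimated on the training set and stored with the model, so
arbitrary sensor orientations and gravity offsets do not dominate the scale.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from gaitkit.core import BilateralRecording, EventKind, EventLog, SamplingSpec, Side

logger = logging.getLogger(__name__)

_F = np.float32


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class NetworkConfig:
    n_blocks: int = 6
    n_filters: int = 64
    kernel_size: int = 3
    dilation_base: int = 2
    dropout_rate: float = 0.1
    n_input_channels: int = 12
    n_classes: int = 5

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("need at least one residual block")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same-length padding")

    @property
    def dilations(self) -> list[int]:
        return [self.dilation_base ** m for m in range(self.n_blocks)]

    @property
    def receptive_field(self) -> int:
        """Input samples influencing one output sample."""
        return 1 + sum(2 * (self.kernel_size - 1) * d for d in self.dilations)


@dataclass(frozen=True)
class LabelEncoding:
    """Target construction: triangular kernels of the given radius around each
    event sample; the null class absorbs the remaining probability mass."""

    smoothing_radius: float = 0.10  # seconds

    #: probability-trace column order; column 0 is the null class
    class_order = ("null", "ic_left", "fc_left", "ic_right", "fc_right")


@dataclass(frozen=True)
class TrainingConfig:
    window_length: float = 10.0  # seconds of signal per training example
    batch_size: int = 8
    learning_rate: float = 1e-3
    max_epochs: int = 30
    patience: int = 8  # early-stopping patience on validation loss
    seed: int = 0
    class_weighting: str = "inverse"  # "inverse" or "none"
    val_fraction: float = 0.2  # used only when no validation set is passed


@dataclass
class ProbabilityTrace:
    """Per-timestep class probabilities; every row sums to 1 within 1e-5."""

    sampling: SamplingSpec
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        rows = self.probabilities.sum(axis=1)
        if self.probabilities.size and not np.allclose(rows, 1.0, atol=1e-5):
            raise ValueError("probability rows must sum to 1 within 1e-5")


# ---------------------------------------------------------------------------
# layers

class _Conv1d:
    """Dilated 1-D convolution with zero same-length padding.

    Tensors are (batch, channels, time); the convolution is computed as a sum
    of per-tap matrix products over shifted slices of the padded input.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, std, size=(c_out, c_in, kernel)).astype(_F)
        self.b = np.zeros(c_out, dtype=_F)
        self.kernel = kernel
        self.dilation = dilation
        self.pad = dilation * (kernel - 1) // 2

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, _, t = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        y = np.zeros((n, self.W.shape[0], t), dtype=_F)
        for k in range(self.kernel):
            o = k * self.dilation
            y += np.matmul(self.W[:, :, k], xp[:, :, o : o + t])
        y += self.b[None, :, None]
        if training:
            self._xp = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        t = dy.shape[2]
        dxp = np.zeros_like(self._xp)
        self.dW = np.zeros_like(self.W)
        for k in range(self.kernel):
            o = k * self.dilation
            self.dW[:, :, k] = np.einsum("not,nit->oi", dy, self._xp[:, :, o : o + t])
            dxp[:, :, o : o + t] += np.matmul(self.W[:, :, k].T, dy)
        self.db = dy.sum(axis=(0, 2))
        self._xp = None
        return dxp[:, :, self.pad : self.pad + t] if self.pad else dxp

    def params(self):
        return [("W", self), ("b", self)]


class _BatchNorm1d:
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=_F)
        self.beta = np.zeros(c, dtype=_F)
        self.running_mean = np.zeros(c, dtype=_F)
        self.running_var = np.ones(c, dtype=_F)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv_std[None, :, None]
        if training:
            self._xhat, self._inv_std, self._m = xhat, inv_std, x.shape[0] * x.shape[2]
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, m = self._xhat, self._inv_std, self._m
        self.dgamma = (dy * xhat).sum(axis=(0, 2))
        self.dbeta = dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[None, :, None]
        # standard batch-norm gradient, reduced over (batch, time)
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        ) * inv_std[None, :, None]
        self._xhat = self._inv_std = None
        return dx.astype(_F)

    def params(self):
        return [("gamma", self), ("beta", self)]


class _ReLU:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class _Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(_F)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx.astype(_F)

    def params(self):
        return []


class _ResidualBlock:
    """[conv -> BN -> ReLU -> dropout] x 2 with a (possibly projected)
    residual connection and a final ReLU."""

    def __init__(self, c_in: int, cfg: NetworkConfig, dilation: int, rng: np.random.Generator):
        c = cfg.n_filters
        self.main = [
            _Conv1d(c_in, c, cfg.kernel_size, dilation, rng),
            _BatchNorm1d(c),
            _ReLU(),
            _Dropout(cfg.dropout_rate, rng),
            _Conv1d(c, c, cfg.kernel_size, dilation, rng),
            _BatchNorm1d(c),
            _ReLU(),
            _Dropout(cfg.dropout_rate, rng),
        ]
        self.proj = _Conv1d(c_in, c, 1, 1, rng) if c_in != c else None
        self.out_relu = _ReLU()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = x
        for layer in self.main:
            y = layer.forward(y, training)
        res = self.proj.forward(x, training) if self.proj is not None else x
        return self.out_relu.forward(y + res, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.out_relu.backward(dy)
        d = dsum
        for layer in reversed(self.main):
            d = layer.backward(d)
        dres = self.proj.backward(dsum) if self.proj is not None else dsum
        return d + dres

    def params(self):
        out = []
        for layer in self.main:
            out.extend(layer.params())
        if self.proj is not None:
            out.extend(self.proj.params())
        return out


class TCNModel:
    """The full network: residual TCN stack, per-timestep dense layer, softmax."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.blocks = []
        c_in = cfg.n_input_channels
        for d in cfg.dilations:
            self.blocks.append(_ResidualBlock(c_in, cfg, d, rng))
            c_in = cfg.n_filters
        self.dense = _Conv1d(cfg.n_filters, cfg.n_classes, 1, 1, rng)
        # per-channel input standardization, fitted during training
        self.input_mean = np.zeros(cfg.n_input_channels, dtype=_F)
        self.input_std = np.ones(cfg.n_input_channels, dtype=_F)
        self.sampling_rate: float | None = None
        self._drop_rng = rng

    @property
    def receptive_field(self) -> int:
        return self.cfg.receptive_field

    # -- forward ------------------------------------------------------------

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.input_mean[None, :, None]) / self.input_std[None, :, None]).astype(_F)

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = self._standardize(x)
        for block in self.blocks:
            y = block.forward(y, training)
        return self.dense.forward(y, training)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities, shape (batch, n_classes, time)."""
        z = self.logits(x, training)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def backward_from_softmax(self, dz: np.ndarray) -> None:
        d = self.dense.backward(dz)
        for block in reversed(self.blocks):
            d = block.backward(d)

    def params(self):
        out = []
        for block in self.blocks:
            out.extend(block.params())
        out.extend(self.dense.params())
        return out

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint (.npz) with the architecture config embedded."""
        arrays = {f"p{i}_{name}": getattr(obj, name) for i, (name, obj) in enumerate(self.params())}
        bn_state = {}
        for i, (name, obj) in enumerate(self.params()):
            if isinstance(obj, _BatchNorm1d) and name == "gamma":
                bn_state[f"bn{i}_mean"] = obj.running_mean
                bn_state[f"bn{i}_var"] = obj.running_var
        meta = json.dumps(
            {"config": asdict(self.cfg), "sampling_rate": self.sampling_rate}
        )
        np.savez(
            path,
            input_mean=self.input_mean,
            input_std=self.input_std,
            meta=np.frombuffer(meta.encode(), dtype=np.uint8),
            **arrays,
            **bn_state,
        )

    @classmethod
    def load(cls, path) -> "TCNModel":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        model = cls(NetworkConfig(**meta["config"]))
        model.sampling_rate = meta["sampling_rate"]
        model.input_mean = data["input_mean"]
        model.input_std = data["input_std"]
        for i, (name, obj) in enumerate(model.params()):
            setattr(obj, name, data[f"p{i}_{name}"])
            if isinstance(obj, _BatchNorm1d) and name == "gamma":
                obj.running_mean = data[f"bn{i}_mean"]
                obj.running_var = data[f"bn{i}_var"]
        return model


def build_model(cfg: NetworkConfig = NetworkConfig(), seed: int = 0) -> TCNModel:
    """Construct an untrained network per the architecture configuration."""
    return TCNModel(cfg, seed=seed)


# ---------------------------------------------------------------------------
# targets

_CLASS_OF_EVENT = {
    (Side.LEFT, EventKind.IC): 1,
    (Side.LEFT, EventKind.FC): 2,
    (Side.RIGHT, EventKind.IC): 3,
    (Side.RIGHT, EventKind.FC): 4,
}


def encode_targets(
    events: EventLog, sampling: SamplingSpec, enc: LabelEncoding = LabelEncoding()
) -> np.ndarray:
    """(n_samples, 5) soft targets: triangular kernels around each event.

    The kernel peaks at 1 at the event sample and decays linearly to 0 at
    +/- smoothing_radius; overlapping same-class kernels take the pointwise
    maximum (with a warning when two same-class events are closer than the
    radius). The null class receives the leftover mass; if event classes
    overlap beyond a total of 1 the row is rescaled so it remains a
    distribution.
    """
    n = sampling.n_samples
    radius = max(int(round(enc.smoothing_radius * sampling.rate)), 1)
    target = np.zeros((n, 5))
    grid = np.arange(n)
    for (side, kind), col in _CLASS_OF_EVENT.items():
        times = events.select(side=side, kind=kind).times()
        if times.size >= 2 and np.min(np.diff(times)) < enc.smoothing_radius:
            warnings.warn(
                f"{side.value} {kind.value} events closer than the smoothing radius; "
                "overlapping kernels take the pointwise maximum"
            )
        for tm in times:
            s = int(round(tm * sampling.rate))
            lo, hi = max(s - radius, 0), min(s + radius + 1, n)
            kernel = 1.0 - np.abs(grid[lo:hi] - s) / radius
            target[lo:hi, col] = np.maximum(target[lo:hi, col], np.clip(kernel, 0.0, 1.0))
    mass = target[:, 1:].sum(axis=1)
    over = mass > 1.0
    if np.any(over):
        target[over, 1:] /= mass[over, None]
        mass = np.minimum(mass, 1.0)
    target[:, 0] = 1.0 - mass
    return target


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"epoch": self.epochs, "train_loss": self.train_loss, "val_loss": self.val_loss}
        )


class _Adam:
    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(getattr(o, n)) for n, o in params]
        self.v = [np.zeros_like(getattr(o, n)) for n, o in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (name, obj) in enumerate(self.params):
            g = getattr(obj, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            new = getattr(obj, name) - self.lr * mh / (np.sqrt(vh) + self.eps)
            setattr(obj, name, new.astype(_F))


def _windows(
    rec: BilateralRecording, targets: np.ndarray, win: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut one recording into windows of ``win`` samples (channels-first);
    a final window anchored at the end covers any remainder."""
    x = rec.stacked().T  # (12, T)
    t = x.shape[1]
    starts = list(range(0, max(t - win, 0) + 1, win))
    if starts and starts[-1] + win < t:
        starts.append(t - win)
    if not starts:  # recording shorter than one window: single truncated window
        starts = [0]
        win = t
    return [(x[:, s : s + win], targets[s : s + win].T) for s in starts]


def _weighted_ce(probs: np.ndarray, targets: np.ndarray, weights: np.ndarray) -> float:
    """Mean per-timestep cross-entropy with per-class weights."""
    logp = np.log(np.clip(probs, 1e-12, None))
    return float(-(weights[None, :, None] * targets * logp).sum(axis=1).mean())


def train(
    model: TCNModel,
    train_data: list[tuple[BilateralRecording, EventLog]],
    tcfg: TrainingConfig = TrainingConfig(),
    val_data: list[tuple[BilateralRecording, EventLog]] | None = None,
    enc: LabelEncoding = LabelEncoding(),
) -> TrainingHistory:
    """Fit the network by per-timestep cross-entropy with early stopping.

    ``train_data``/``val_data`` are (recording, ground-truth events) pairs;
    when no validation set is given, the last ``val_fraction`` of the training
    recordings (whole subjects, never split windows) is held out. The best
    validation parameters are restored at the end. Deterministic given
    ``tcfg.seed``.
    """
    if not train_data:
        raise ValueError("empty training set")
    rate = train_data[0][0].sampling.rate
    win = int(round(tcfg.window_length * rate))
    if win < model.receptive_field:
        raise ValueError(
            f"window of {win} samples is shorter than the receptive field "
            f"({model.receptive_field} samples)"
        )
    if val_data is None:
        n_val = max(int(round(tcfg.val_fraction * len(train_data))), 1)
        if n_val >= len(train_data):
            raise ValueError("not enough recordings to hold out a validation set")
        val_data = train_data[-n_val:]
        train_data = train_data[:-n_val]

    def collect(data):
        out = []
        for rec, ev in data:
            out.extend(_windows(rec, encode_targets(ev, rec.sampling, enc), win))
        return out

    train_w = collect(train_data)
    val_w = collect(val_data)
    model.sampling_rate = rate

    xs = np.concatenate([w[0] for w in train_w], axis=1)
    model.input_mean = xs.mean(axis=1).astype(_F)
    model.input_std = np.maximum(xs.std(axis=1), 1e-6).astype(_F)

    if tcfg.class_weighting == "inverse":
        freq = np.stack([w[1] for w in train_w]).mean(axis=(0, 2))
        weights = 1.0 / np.maximum(freq, 1e-6)
        weights /= (weights * freq).sum()  # unit average weight per timestep
    elif tcfg.class_weighting == "none":
        weights = np.ones(model.cfg.n_classes)
    else:
        raise ValueError(f"unknown class_weighting {tcfg.class_weighting!r}")
    weights = weights.astype(_F)

    rng = np.random.default_rng(tcfg.seed)
    model._drop_rng = np.random.default_rng(tcfg.seed + 1)
    for block in model.blocks:
        for layer in block.main:
            if isinstance(layer, _Dropout):
                layer.rng = model._drop_rng

    opt = _Adam(model.params(), tcfg.learning_rate)
    history = TrainingHistory()
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    best_bn: list[tuple[np.ndarray, np.ndarray]] = []
    since_best = 0

    def snapshot():
        state = [getattr(o, n).copy() for n, o in model.params()]
        bn = [
            (o.running_mean.copy(), o.running_var.copy())
            for n, o in model.params()
            if isinstance(o, _BatchNorm1d) and n == "gamma"
        ]
        return state, bn

    def restore(state, bn):
        for (n, o), v in zip(model.params(), state):
            setattr(o, n, v.copy())
        it = iter(bn)
        for n, o in model.params():
            if isinstance(o, _BatchNorm1d) and n == "gamma":
                o.running_mean, o.running_var = (a.copy() for a in next(it))

    def evaluate(wins) -> float:
        total, count = 0.0, 0
        for i in range(0, len(wins), tcfg.batch_size):
            batch = wins[i : i + tcfg.batch_size]
            x = np.stack([b[0] for b in batch]).astype(_F)
            y = np.stack([b[1] for b in batch]).astype(_F)
            probs = model.forward(x, training=False)
            total += _weighted_ce(probs, y, weights) * len(batch)
            count += len(batch)
        return total / count

    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(len(train_w))
        ep_loss, n_batches = 0.0, 0
        for i in range(0, len(order), tcfg.batch_size):
            idx = order[i : i + tcfg.batch_size]
            x = np.stack([train_w[j][0] for j in idx]).astype(_F)
            y = np.stack([train_w[j][1] for j in idx]).astype(_F)
            probs = model.forward(x, training=True)
            ep_loss += _weighted_ce(probs, y, weights)
            n_batches += 1
            # gradient of weighted cross-entropy through the softmax
            wt = weights[None, :, None] * y
            dz = (probs * wt.sum(axis=1, keepdims=True) - wt) / (y.shape[0] * y.shape[2])
            model.backward_from_softmax(dz.astype(_F))
            opt.step()
        val_loss = evaluate(val_w)
        history.epochs.append(epoch)
        history.train_loss.append(ep_loss / n_batches)
        history.val_loss.append(val_loss)
        logger.info("epoch %d: train %.4f val %.4f", epoch, ep_loss / n_batches, val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state, best_bn = snapshot()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > tcfg.patience:
                break
    if best_state is not None:
        restore(best_state, best_bn)
    return history


# ---------------------------------------------------------------------------
# inference

_MAX_FULL_PASS = 20_000  # samples; longer recordings are stitched from windows


def predict_probabilities(model: TCNModel, rec: BilateralRecording) -> ProbabilityTrace:
    """Per-timestep class probabilities for a whole recording.

    Recordings longer than ~200 s are processed in overlapping windows with
    centered stitching: the overlap equals the receptive field and only the
    central region of each window is kept, which removes padding-boundary
    artifacts. Output length equals input length.
    """
    x = rec.stacked().T  # (12, T)
    if x.shape[0] != model.cfg.n_input_channels:
        raise ValueError(f"expected {model.cfg.n_input_channels} channels, got {x.shape[0]}")
    if model.sampling_rate is not None and rec.sampling.rate != model.sampling_rate:
        raise ValueError(
            f"recording rate {rec.sampling.rate} differs from training rate {model.sampling_rate}"
        )
    t = x.shape[1]
    margin = model.receptive_field
    win = _MAX_FULL_PASS
    if t <= win:
        probs = model.forward(x[None], training=False)[0]
    else:
        probs = np.zeros((model.cfg.n_classes, t), dtype=_F)
        step = win - 2 * margin
        start = 0
        while start < t:
            s = min(start, t - win)
            block = model.forward(x[None, :, s : s + win], training=False)[0]
            keep_lo = 0 if s == 0 else margin
            keep_hi = win if s + win >= t else win - margin
            a, b = s + keep_lo, s + keep_hi
            probs[:, a:b] = block[:, keep_lo:keep_hi]
            if s + win >= t:
                break
            start = s + step
    return ProbabilityTrace(rec.sampling, probs.T.astype(float))
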