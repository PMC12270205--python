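"""3D-DenseNet brain-age regressor: architecture, parameter bookkeeping, training.

The network maps a single-channel 3D volume to one scalar (brain age, years):

    stem 5x5x5 conv (1 -> C0) -> norm -> ReLU
    -> [dense block_i -> transition]x3 -> dense block_4
    -> 3x3x3 conv -> norm -> ReLU (optional, ``final_conv_width``)
    -> global average pooling -> fully connected scalar head

Each dense layer is norm -> ReLU -> 1x1x1 conv (c -> s*c) -> norm -> ReLU
-> 3x3x3 conv (s*c -> k), appending its k output channels to the block's
running feature map. The 1x1x1 bottleneck scales with the *current*
in-channel dimension (factor ``bottleneck_scale``) rather than a fixed
multiple of the growth rate. Transitions are norm -> ReLU -> 1x1x1 conv
with channel compression, followed by 2x average pooling.

``count_parameters`` mirrors the construction in closed form so the full
scale configuration can be resolved and audited without allocating it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters of the 3D-DenseNet regressor.

    ``bottleneck_scale`` (s) multiplies the running in-channel dimension in
    the 1x1x1 bottleneck; ``compression`` is the channel fraction kept by
    transitions (floor). ``final_conv_width=None`` omits the final 3x3x3
    convolution, so the head pools the last block's channels directly.
    Bias toggles follow the convention that convolutions immediately
    followed by a normalization carry no bias.
    """

    stem_width: int = 8
    stem_kernel: int = 5
    stem_stride: int = 2  # downsampling stem; no effect on parameter counts
    block_layers: tuple = (3, 6, 12, 8)
    growth_rate: int = 4
    bottleneck_scale: int = 1
    compression: float = 0.5
    final_conv_width: int | None = 16
    stem_bias: bool = True
    final_bias: bool = True
    bottleneck_bias: bool = False
    growth_bias: bool = False
    transition_bias: bool = False

    def validate(self) -> None:
        if self.stem_width < 1:
            raise ValueError("stem_width must be >= 1")
        if self.stem_kernel % 2 != 1 or self.stem_kernel < 1:
            raise ValueError("stem_kernel must be odd and positive")
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if self.bottleneck_scale < 1:
            raise ValueError("bottleneck_scale must be >= 1")
        if not (0.0 < self.compression <= 1.0):
            raise ValueError("compression must be in (0, 1]")
        if self.final_conv_width is not None and self.final_conv_width < 1:
            raise ValueError("final_conv_width must be >= 1 or None")
        if any(l < 0 for l in self.block_layers):
            raise ValueError("block_layers must be non-negative")
        # trace channels so degenerate compressions fail loudly
        for where, c in self.channel_trace():
            if c < 1:
                raise ValueError(f"non-positive channel width at {where}: {c}")

    def channel_trace(self):
        """Yield (location, channels) pairs along the network."""
        c = self.stem_width
        yield "stem", c
        for bi, layers in enumerate(self.block_layers):
            c = c + layers * self.growth_rate
            yield f"block{bi + 1}", c
            if bi < len(self.block_layers) - 1:
                c = int(math.floor(self.compression * c))
                yield f"transition{bi + 1}", c
        if self.final_conv_width is not None:
            yield "final_conv", self.final_conv_width


#: Full-scale reference configuration. Resolved once by
#: :func:`resolve_reference_config` against the published total of
#: 251,098,737 trainable parameters for dense blocks of (3, 6, 12, 8) layers.
REFERENCE_CONFIG = NetConfig(
    stem_width=448,
    stem_kernel=5,
    block_layers=(3, 6, 12, 8),
    growth_rate=156,
    bottleneck_scale=1,
    compression=0.5,
    final_conv_width=156,
)

REFERENCE_PARAMETER_COUNT = 251_098_737


def load_reference_config() -> NetConfig:
    """Read the packaged reference-architecture YAML into a NetConfig."""
    import importlib.resources as res

    import yaml

    payload = yaml.safe_load(
        res.files("neurobag").joinpath("data/reference_net.yaml").read_text())
    payload["block_layers"] = tuple(payload["block_layers"])
    return NetConfig(**payload)


def load_train_config():
    """Read the packaged training-protocol YAML into a TrainConfig."""
    import importlib.resources as res

    import yaml

    payload = yaml.safe_load(
        res.files("neurobag").joinpath("data/train_config.yaml").read_text())
    return TrainConfig(**payload)


# ---------------------------------------------------------------------------
# Closed-form parameter counting
# ---------------------------------------------------------------------------

def count_parameters(config: NetConfig) -> int:
    """Closed-form count of trainable parameters for ``config``.

    Counts convolution weights (+ biases where enabled), normalization
    affine pairs (2 per channel), and the fully connected head; must agree
    with the instantiated model's count for every valid configuration.
    """
    config.validate()
    c0 = config.stem_width
    k = config.growth_rate
    s = config.bottleneck_scale
    total = config.stem_kernel ** 3 * c0 + (c0 if config.stem_bias else 0)
    total += 2 * c0  # stem norm
    c = c0
    for bi, layers in enumerate(config.block_layers):
        for _ in range(layers):
            mid = s * c
            total += 2 * c  # layer norm 1
            total += c * mid + (mid if config.bottleneck_bias else 0)  # 1x1x1
            total += 2 * mid  # layer norm 2
            total += 27 * mid * k + (k if config.growth_bias else 0)  # 3x3x3
            c += k
        if bi < len(config.block_layers) - 1:
            out = int(math.floor(config.compression * c))
            total += 2 * c  # transition norm
            total += c * out + (out if config.transition_bias else 0)
            c = out
    if config.final_conv_width is not None:
        f = config.final_conv_width
        total += 27 * c * f + (f if config.final_bias else 0)
        total += 2 * f  # final norm
        c = f
    total += c + 1  # fully connected scalar head
    return total


def resolve_reference_config(block_layers=(3, 6, 12, 8), search_grid=None,
                             target=REFERENCE_PARAMETER_COUNT):
    """Enumerate a hyperparameter grid for configs matching ``target`` exactly.

    ``search_grid`` maps NetConfig field names to candidate value lists
    (defaults cover stem_width / growth_rate / bottleneck_scale /
    compression / final_conv_width and both conv-bias toggles). Returns
    ``(matches, nearest)``: all exact matches, and the five nearest
    candidates as (|count - target|, config, count) when no exact match is
    found (both lists are always populated for reporting).
    """
    if search_grid is None:
        search_grid = {
            "stem_width": [REFERENCE_CONFIG.stem_width],
            "growth_rate": [REFERENCE_CONFIG.growth_rate],
            "bottleneck_scale": [REFERENCE_CONFIG.bottleneck_scale],
            "compression": [REFERENCE_CONFIG.compression],
            "final_conv_width": [REFERENCE_CONFIG.final_conv_width],
        }
    keys = list(search_grid)
    matches, candidates = [], []

    def rec(i, kwargs):
        if i == len(keys):
            cfg = NetConfig(block_layers=tuple(block_layers), **kwargs)
            try:
                n = count_parameters(cfg)
            except ValueError:
                return
            if n == target:
                matches.append(cfg)
            candidates.append((abs(n - target), cfg, n))
            return
        for v in search_grid[keys[i]]:
            rec(i + 1, {**kwargs, keys[i]: v})

    rec(0, {})
    candidates.sort(key=lambda t: t[0])
    return matches, candidates[:5]


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

class _DenseLayer(nn.Module):
    def __init__(self, c_in, config, rng, dtype, name):
        s, k = config.bottleneck_scale, config.growth_rate
        self.body = nn.Sequential([
            nn.BatchNorm3d(c_in, dtype=dtype),
            nn.ReLU(),
            nn.Conv3d(c_in, s * c_in, 1, bias=config.bottleneck_bias, rng=rng, dtype=dtype),
            nn.BatchNorm3d(s * c_in, dtype=dtype),
            nn.ReLU(),
            nn.Conv3d(s * c_in, k, 3, bias=config.growth_bias, rng=rng, dtype=dtype),
        ], name=name)

    def parameters(self):
        yield from self.body.parameters()

    def forward(self, x, training=False):
        return self.body.forward(x, training=training)

    def backward(self, dout):
        return self.body.backward(dout)


class _DenseBlock(nn.Module):
    def __init__(self, c_in, n_layers, config, rng, dtype, name):
        self.layers = []
        c = c_in
        for i in range(n_layers):
            self.layers.append(_DenseLayer(c, config, rng, dtype, f"{name}.layer{i}"))
            c += config.growth_rate
        self.c_out = c
        self._widths = None

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()

    def forward(self, x, training=False):
        widths = [x.shape[1]]
        for layer in self.layers:
            new = layer.forward(x, training=training)
            x = np.concatenate([x, new], axis=1)
            widths.append(x.shape[1])
        self._widths = widths
        return x

    def backward(self, dout):
        widths = self._widths
        for layer, w_in in zip(reversed(self.layers), reversed(widths[:-1])):
            dnew = dout[:, w_in:]
            dout = dout[:, :w_in].copy() + layer.backward(dnew)
        self._widths = None
        return dout


class DenseNet3d(nn.Module):
    """The assembled regressor; ``forward`` returns (N, 1) brain ages."""

    def __init__(self, config: NetConfig, rng=None, dtype=np.float64):
        config.validate()
        self.config = config
        rng = rng or np.random.default_rng(0)
        stem = [
            nn.Conv3d(1, config.stem_width, config.stem_kernel,
                      bias=config.stem_bias, stride=config.stem_stride,
                      rng=rng, dtype=dtype),
            nn.BatchNorm3d(config.stem_width, dtype=dtype),
            nn.ReLU(),
        ]
        self.trunk_layers = stem
        c = config.stem_width
        for bi, n_layers in enumerate(config.block_layers):
            block = _DenseBlock(c, n_layers, config, rng, dtype, f"block{bi + 1}")
            self.trunk_layers.append(block)
            c = block.c_out
            if bi < len(config.block_layers) - 1:
                out = int(math.floor(config.compression * c))
                self.trunk_layers += [
                    nn.BatchNorm3d(c, dtype=dtype),
                    nn.ReLU(),
                    nn.Conv3d(c, out, 1, bias=config.transition_bias, rng=rng, dtype=dtype),
                    nn.AvgPool3d(),
                ]
                c = out
        if config.final_conv_width is not None:
            f = config.final_conv_width
            self.trunk_layers += [
                nn.Conv3d(c, f, 3, bias=config.final_bias, rng=rng, dtype=dtype),
                nn.BatchNorm3d(f, dtype=dtype),
                nn.ReLU(),
            ]
            c = f
        self.trunk = nn.Sequential(self.trunk_layers, name="trunk")
        self.pool = nn.GlobalAvgPool()
        self.head = nn.Linear(c, 1, rng=rng, dtype=dtype, name="head")
        self.stem_conv = self.trunk_layers[0]

    def parameters(self):
        yield from self.trunk.parameters()
        yield from self.head.parameters()

    def forward(self, x, training=False):
        if x.ndim == 4:
            x = x[:, None]
        h = self.trunk.forward(x, training=training)
        h = self.pool.forward(h, training=training)
        return self.head.forward(h, training=training)

    def backward(self, dout):
        dh = self.head.backward(dout)
        dh = self.pool.backward(dh)
        return self.trunk.backward(dh)

    def input_gradient(self, volume: np.ndarray) -> np.ndarray:
        """Gradient of the scalar output with respect to one input volume."""
        x = np.asarray(volume)[None, None]
        self.stem_conv.compute_input_grad = True
        self.forward(x, training=False)
        for _, p in self.parameters():
            p.zero_grad()
        dx = self.backward(np.ones((1, 1), dtype=x.dtype))
        for _, p in self.parameters():
            p.zero_grad()
        return dx[0, 0]


def build_model(config: NetConfig, seed: int = 42, dtype=np.float64) -> DenseNet3d:
    """Instantiate the regressor with seeded He-style initialization."""
    return DenseNet3d(config, rng=np.random.default_rng(seed), dtype=dtype)


def predict_brain_age(model: DenseNet3d, volumes, batch_size: int = 8) -> np.ndarray:
    """Predicted brain age (years) per volume, in evaluation mode.

    Predictions are per-scan and therefore independent of batch
    composition and order.
    """
    vols = np.asarray(volumes)
    if vols.ndim == 3:
        vols = vols[None]
    out = []
    for i in range(0, len(vols), batch_size):
        out.append(model.forward(vols[i:i + batch_size], training=False)[:, 0])
    return np.concatenate(out) if out else np.empty(0)


# ---------------------------------------------------------------------------
# Staged training protocol
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Staged training protocol: cycles of epochs with plateau-triggered
    learning-rate decay, patience-based early stopping, and best-state
    checkpointing. Defaults mirror the full-scale protocol."""

    cycles: int = 5
    epochs_per_cycle: int = 15
    batch_size: int = 8
    lr0: float = 5e-6
    lr_decay: float = 0.7
    patience: int = 6
    seed: int = 42
    #: start the scalar head at the training-set mean age, so the MAE
    #: objective optimizes deviations from the mean rather than spending
    #: epochs recovering the age scale
    init_head_bias: bool = True

    def validate(self):
        if min(self.cycles, self.epochs_per_cycle, self.batch_size, self.patience) < 1:
            raise ValueError("cycles, epochs_per_cycle, batch_size, patience must be >= 1")
        if self.lr0 <= 0 or not (0 < self.lr_decay <= 1):
            raise ValueError("lr0 must be > 0 and lr_decay in (0, 1]")


@dataclass
class TrainState:
    train_history: list = field(default_factory=list)
    val_history: list = field(default_factory=list)
    lr: float = 0.0
    best_val: float = math.inf
    best_epoch: int = -1
    stopped_early: bool = False
    best_state: dict | None = None
    epochs_run: int = 0


class StagedSchedule:
    """Early-stopping and cycle-wise learning-rate decay bookkeeping.

    The no-improvement counter is epoch-global (it does not reset at cycle
    boundaries, only on improvement). At each cycle boundary, if no epoch
    of the completed cycle achieved a new best validation loss, the
    learning rate is multiplied by ``lr_decay``.
    """

    def __init__(self, tc: TrainConfig):
        self.tc = tc
        self.lr = tc.lr0
        self.best = math.inf
        self.best_epoch = -1
        self.since_improve = 0
        self.improved_this_cycle = False

    def observe(self, epoch: int, val_loss: float) -> dict:
        """Record one epoch's validation loss; returns flags."""
        improved = val_loss < self.best
        if improved:
            self.best = val_loss
            self.best_epoch = epoch
            self.since_improve = 0
            self.improved_this_cycle = True
        else:
            self.since_improve += 1
        stop = self.since_improve >= self.tc.patience
        decay = False
        end_of_cycle = (epoch + 1) % self.tc.epochs_per_cycle == 0
        if end_of_cycle and not stop:
            if not self.improved_this_cycle:
                self.lr *= self.tc.lr_decay
                decay = True
            self.improved_this_cycle = False
        return {"improved": improved, "stop": stop, "decayed": decay}


def staged_train(model: DenseNet3d, train_set, val_set, tc: TrainConfig) -> TrainState:
    """Train with MAE loss under the staged protocol; fully seeded.

    ``train_set`` and ``val_set`` are (volumes, ages) pairs with volumes
    shaped (N, D, H, W). The best-validation state is checkpointed on
    every improvement and restored into ``model`` at the end.
    """
    tc.validate()
    x_tr, y_tr = np.asarray(train_set[0]), np.asarray(train_set[1], dtype=float)
    x_va, y_va = np.asarray(val_set[0]), np.asarray(val_set[1], dtype=float)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("training and validation sets must be non-empty")
    dtype = model.head.w.value.dtype
    x_tr = x_tr.astype(dtype, copy=False)
    x_va = x_va.astype(dtype, copy=False)
    rng = np.random.default_rng(tc.seed)
    model.stem_conv.compute_input_grad = False  # no saliency needed while training
    if tc.init_head_bias:
        model.head.b.value[...] = y_tr.mean()
    params = [p for _, p in model.parameters()]
    opt = nn.Adam(params, lr=tc.lr0)
    sched = StagedSchedule(tc)
    state = TrainState(lr=tc.lr0)

    def val_loss():
        pred = predict_brain_age(model, x_va, batch_size=tc.batch_size)
        return float(np.mean(np.abs(pred - y_va)))

    total_epochs = tc.cycles * tc.epochs_per_cycle
    for epoch in range(total_epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), tc.batch_size):
            idx = order[i:i + tc.batch_size]
            pred = model.forward(x_tr[idx], training=True)
            loss, dpred = nn.mae_loss(pred[:, 0], y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dpred[:, None])
            opt.lr = sched.lr
            opt.step()
            losses.append(loss)
        vl = val_loss()
        if not np.isfinite(vl):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        state.train_history.append(float(np.mean(losses)))
        state.val_history.append(vl)
        state.epochs_run = epoch + 1
        flags = sched.observe(epoch, vl)
        if flags["improved"]:
            state.best_val = vl
            state.best_epoch = epoch
            state.best_state = nn.state_dict(model)
        state.lr = sched.lr
        if flags["stop"]:
            state.stopped_early = True
            break
    if state.best_state is not None:
        nn.load_state_dict(model, state.best_state)
    return state
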