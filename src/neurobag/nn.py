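"""Minimal 3D convolutional network toolkit with explicit forward/backward passes.

Implements exactly the layer set a 3D-DenseNet brain-age regressor needs:
stride-1 "same" 3D convolutions, batch normalization, ReLU, 2x average
pooling, global average pooling, and a fully connected head, plus an Adam
optimizer and a mean-absolute-error loss. Every layer caches what its
backward pass needs, so gradients are available both for the parameters
(training) and for the input volume (saliency maps).

Arrays are laid out as (N, C, D, H, W). Float64 is the default for the
sake of gradient checks; float32 is available for large instantiations.
"""

from __future__ import annotations

import copy

import numpy as np



class Param:
    """A trainable tensor with a lazily allocated gradient buffer."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = None

    def add_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: subclasses define forward(x, training) and backward(dout)."""

    def parameters(self):
        """Yield (name, Param) pairs in a stable order."""
        return
        yield

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def num_parameters(self) -> int:
        return sum(p.size for _, p in self.parameters())


def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    if not p:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


def _out_len(n: int, stride: int) -> int:
    return (n + stride - 1) // stride


def _conv3d_padded(xp: np.ndarray, w: np.ndarray, b, out_shape, stride=1) -> np.ndarray:
    """Strided 'same' 3D convolution given the pre-padded input.

    Accumulates one GEMM per kernel offset, which keeps temporaries at a
    single channel-plane instead of materializing the full im2col tensor.
    """
    n, _, d, h, wd = out_shape
    k = w.shape[2]
    c_out = w.shape[0]
    do, ho, wo = _out_len(d, stride), _out_len(h, stride), _out_len(wd, stride)
    v = do * ho * wo
    out = np.zeros((n, c_out, v), dtype=xp.dtype)
    s = stride
    for i in range(k):
        for j in range(k):
            for l in range(k):
                xs = xp[:, :, i:i + d:s, j:j + h:s, l:l + wd:s].reshape(n, -1, v)
                out += np.matmul(w[:, :, i, j, l], xs)
    out = out.reshape(n, c_out, do, ho, wo)
    if b is not None:
        out += b[None, :, None, None, None]
    return out


def _conv3d(x: np.ndarray, w: np.ndarray, b, stride=1) -> np.ndarray:
    return _conv3d_padded(_pad_same(x, w.shape[2]), w, b, x.shape, stride=stride)


class Conv3d(Module):
    def __init__(self, c_in, c_out, kernel, bias=True, stride=1, rng=None,
                 dtype=np.float64, name="conv"):
        if kernel % 2 != 1:
            raise ValueError("only odd kernels are supported ('same' padding)")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel ** 3
        std = np.sqrt(2.0 / fan_in)
        self.w = Param(rng.normal(0.0, std, (c_out, c_in, kernel, kernel, kernel)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype)) if bias else None
        self.stride = int(stride)
        self.name = name
        #: set False to skip the (expensive) input gradient, e.g. for the
        #: first layer during training when no saliency map is needed
        self.compute_input_grad = True
        self._xp = None
        self._shape = None

    def parameters(self):
        yield f"{self.name}.w", self.w
        if self.b is not None:
            yield f"{self.name}.b", self.b

    def forward(self, x, training=False):
        k = self.w.value.shape[2]
        self._shape = x.shape
        self._xp = _pad_same(x, k)
        return _conv3d_padded(self._xp, self.w.value,
                              None if self.b is None else self.b.value,
                              x.shape, stride=self.stride)

    def backward(self, dout):
        xp = self._xp
        n, _, d, h, wd = self._shape
        k = self.w.value.shape[2]
        s = self.stride
        c_out = dout.shape[1]
        v = dout.shape[2] * dout.shape[3] * dout.shape[4]
        dout_f = dout.reshape(n, c_out, v)
        dw = np.empty_like(self.w.value)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, :, i:i + d:s, j:j + h:s, l:l + wd:s].reshape(n, -1, v)
                    # dw[o, c, i, j, l] = sum_{n, v} dout[n, o, v] * xs[n, c, v]
                    dw[:, :, i, j, l] = np.tensordot(dout_f, xs, axes=([0, 2], [0, 2]))
        self.w.add_grad(dw)
        if self.b is not None:
            self.b.add_grad(dout.sum(axis=(0, 2, 3, 4)))
        self._xp = None
        if not self.compute_input_grad:
            return None
        # Input gradient: zero-stuff dout back to input resolution, then
        # correlate with the spatially flipped, transposed kernel.
        if s > 1:
            up = np.zeros((n, c_out, d, h, wd), dtype=dout.dtype)
            up[:, :, ::s, ::s, ::s] = dout
            dout = up
        w_flip = np.flip(self.w.value, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4)
        return _conv3d(dout, np.ascontiguousarray(w_flip), None)


class BatchNorm3d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1, dtype=np.float64, name="norm"):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.name = name
        self._cache = None

    def parameters(self):
        yield f"{self.name}.gamma", self.gamma
        yield f"{self.name}.beta", self.beta

    def forward(self, x, training=False):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) / std[None, :, None, None, None]
        self._cache = (xhat, std, training)
        return self.gamma.value[None, :, None, None, None] * xhat + \
            self.beta.value[None, :, None, None, None]

    def backward(self, dout):
        xhat, std, training = self._cache
        axes = (0, 2, 3, 4)
        self.gamma.add_grad((dout * xhat).sum(axis=axes))
        self.beta.add_grad(dout.sum(axis=axes))
        g = self.gamma.value[None, :, None, None, None]
        if not training:
            self._cache = None
            return dout * g / std[None, :, None, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        dxhat = dout * g
        mean_dxhat = dxhat.mean(axis=axes)[None, :, None, None, None]
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes)[None, :, None, None, None]
        dx = (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std[None, :, None, None, None]
        self._cache = None
        return dx


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class AvgPool3d(Module):
    """2x2x2 average pooling with stride 2; odd trailing slices are trimmed."""

    def __init__(self):
        self._shape = None

    def forward(self, x, training=False):
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        if min(d2, h2, w2) < 1:
            raise ValueError(f"volume {x.shape[2:]} too small to pool")
        xt = x[:, :, : d2 * 2, : h2 * 2, : w2 * 2]
        self._shape = x.shape
        return xt.reshape(n, c, d2, 2, h2, 2, w2, 2).mean(axis=(3, 5, 7))

    def backward(self, dout):
        n, c, d, h, w = self._shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        dx = np.zeros(self._shape, dtype=dout.dtype)
        up = np.repeat(np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3), 2, axis=4) / 8.0
        dx[:, :, : d2 * 2, : h2 * 2, : w2 * 2] = up
        self._shape = None
        return dx


class GlobalAvgPool(Module):
    def __init__(self):
        self._shape = None

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        n, c, d, h, w = self._shape
        dx = np.broadcast_to(dout[:, :, None, None, None] / (d * h * w), self._shape).copy()
        self._shape = None
        return dx


class Linear(Module):
    def __init__(self, c_in, c_out, rng=None, dtype=np.float64, name="fc"):
        rng = rng or np.random.default_rng(0)
        std = 1.0 / np.sqrt(c_in)
        self.w = Param(rng.normal(0.0, std, (c_out, c_in)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.name = name
        self._x = None

    def parameters(self):
        yield f"{self.name}.w", self.w
        yield f"{self.name}.b", self.b

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout):
        self.w.add_grad(dout.T @ self._x)
        self.b.add_grad(dout.sum(axis=0))
        dx = dout @ self.w.value
        self._x = None
        return dx


class Sequential(Module):
    def __init__(self, layers, name="seq"):
        self.layers = list(layers)
        self.name = name

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for n, p in layer.parameters():
                yield f"{self.name}[{i}].{n}", p

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam optimizer over a list of Param objects."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def mae_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error and its gradient with respect to pred."""
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / diff.size
    return loss, grad


def state_dict(module: Module) -> dict:
    return {n: p.value.copy() for n, p in module.parameters()}


def load_state_dict(module: Module, state: dict) -> None:
    for n, p in module.parameters():
        p.value = state[n].copy()


def clone_state(module: Module) -> dict:
    return copy.deepcopy(state_dict(module))
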