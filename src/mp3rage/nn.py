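"""Minimal CPU neural-network engine for the patch calibration model.

A small, self-contained stack of layers (3x3/1x1 convolutions via im2col,
batch normalization, ReLU, residual blocks, global average pooling, affine
head) with manual backpropagation and an Adam optimizer, in float32 numpy.
It exists to train the 18-layer residual regressor on tiny T1 patches on a
single CPU; it is not a general-purpose autodiff framework.

All parameter initialization is seeded (He-normal fan-in for convolutions),
so two builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "GlobalAvgPool", "Linear",
           "Sequential", "BasicBlock", "ResNetRegressor", "Adam", "mse_loss"]

_F = np.float32


class Module:
    def parameters(self) -> list[dict]:
        return []

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the module's state (weights + BN statistics)."""
        return [p["value"] for p in self.parameters()]

    def forward(self, x, train: bool):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]           # (n, c, ho, wo, k, k)
    # single-GEMM layout: (c*k*k, n*ho*wo)
    cols = windows.transpose(1, 4, 5, 0, 2, 3).reshape(c * k * k, n * ho * wo)
    return np.ascontiguousarray(cols), (ho, wo, hp, wp)


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, geom):
    n, c, h, w = x_shape
    ho, wo, hp, wp = geom
    dx = np.zeros((n, c, hp, wp), dtype=_F)
    dwin = dcols.reshape(c, k, k, n, ho, wo).transpose(3, 0, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dwin[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:hp - pad, pad:wp - pad]
    return dx


class Conv2d(Module):
    """k x k convolution (no bias; batch norm follows), He-normal init."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = k // 2
        std = np.sqrt(2.0 / (c_in * k * k))
        self.w = {"value": rng.normal(0, std, (c_out, c_in * k * k)).astype(_F), "grad": None}

    def parameters(self):
        return [self.w]

    def forward(self, x, train):
        self._x_shape = x.shape
        cols, self._geom = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        n = x.shape[0]
        ho, wo = self._geom[0], self._geom[1]
        y = self.w["value"] @ cols                        # (c_out, n*L)
        return np.ascontiguousarray(
            y.reshape(self.c_out, n, ho * wo).transpose(1, 0, 2)
        ).reshape(n, self.c_out, ho, wo)

    def backward(self, grad):
        n = grad.shape[0]
        g = np.ascontiguousarray(
            grad.reshape(n, self.c_out, -1).transpose(1, 0, 2)
        ).reshape(self.c_out, -1)                          # (c_out, n*L)
        self.w["grad"] = g @ self._cols.T
        dcols = self.w["value"].T @ g
        self._cols = None
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad, self._geom)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = {"value": np.ones(c, dtype=_F), "grad": None}
        self.beta = {"value": np.zeros(c, dtype=_F), "grad": None}
        self.running_mean = np.zeros(c, dtype=_F)
        self.running_var = np.ones(c, dtype=_F)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.gamma["value"], self.beta["value"], self.running_mean, self.running_var]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(_F)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(_F)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(_F)
        self._xhat = (x - mean[None, :, None, None]) * self._inv_std[None, :, None, None]
        return self.gamma["value"][None, :, None, None] * self._xhat + self.beta["value"][None, :, None, None]

    def backward(self, grad):
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma["grad"] = np.einsum("nchw,nchw->c", grad, self._xhat)
        self.beta["grad"] = grad.sum(axis=(0, 2, 3))
        g = self.gamma["value"][None, :, None, None]
        dxhat = grad * g
        # standard batch-norm backward (training statistics)
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - sum_dxhat / m - self._xhat * sum_dxhat_xhat / m) * self._inv_std[None, :, None, None]
        self._xhat = None
        return dx.astype(_F)


class ReLU(Module):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class GlobalAvgPool(Module):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._shape).astype(_F)


class Linear(Module):
    """Affine layer; ``zero_init`` starts the weights at zero so a
    regression head begins as a pure-bias (constant) predictor."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((c_in, c_out), dtype=_F)
        else:
            w = rng.normal(0, np.sqrt(2.0 / c_in), (c_in, c_out)).astype(_F)
        self.w = {"value": w, "grad": None}
        self.b = {"value": np.zeros(c_out, dtype=_F), "grad": None}

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w["value"] + self.b["value"]

    def backward(self, grad):
        self.w["grad"] = self._x.T @ grad
        self.b["grad"] = grad.sum(axis=0)
        dx = grad @ self.w["value"].T
        self._x = None
        return dx


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def state_arrays(self):
        return [a for l in self.layers for a in l.state_arrays()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class BasicBlock(Module):
    """Two 3x3 conv-BN units with a residual shortcut (1x1 conv when the
    channel count or stride changes)."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, rng)
        self.bn2 = BatchNorm2d(c_out)
        if c_in != c_out or stride != 1:
            self.shortcut = Sequential(Conv2d(c_in, c_out, 1, stride, rng), BatchNorm2d(c_out))
        else:
            self.shortcut = None
        self.relu_out = ReLU()

    def _children(self):
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]
        if self.shortcut is not None:
            out.append(self.shortcut)
        return out

    def parameters(self):
        return [p for c in self._children() for p in c.parameters()]

    def state_arrays(self):
        return [a for c in self._children() for a in c.state_arrays()]

    def forward(self, x, train):
        y = self.conv1.forward(x, train)
        y = self.bn1.forward(y, train)
        y = self.relu1.forward(y, train)
        y = self.conv2.forward(y, train)
        y = self.bn2.forward(y, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu_out.forward(y + s, train)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        dy = self.bn2.backward(grad)
        dy = self.conv2.backward(dy)
        dy = self.relu1.backward(dy)
        dy = self.bn1.backward(dy)
        dx = self.conv1.backward(dy)
        ds = grad if self.shortcut is None else self.shortcut.backward(grad)
        return dx + ds


def _out_extent(extent: int, stride: int) -> int:
    return (extent + 2 - 3) // stride + 1   # k=3, pad=1


class ResNetRegressor(Module):
    """18-layer residual regressor adapted to tiny in-plane patches.

    Four stages of two basic blocks with widths (w, 2w, 4w, 8w); a 3x3
    stride-1 stem replaces the usual 7x7 stem and max-pool, and stage
    downsampling falls back to stride 1 whenever the running spatial
    extent is below 4.  Global average pooling feeds a single-output
    affine head.
    """

    def __init__(self, in_channels: int = 1, patch_size: int = 5,
                 base_width: int = 64, seed: int = 0):
        if patch_size < 1 or patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 1")
        rng = np.random.Generator(np.random.Philox(key=(np.uint64(seed & 0x7FFFFFFF),
                                                        np.uint64(0xD4))))
        self.in_channels = in_channels
        self.patch_size = patch_size
        w = base_width
        extent = patch_size
        layers = [Conv2d(in_channels, w, 3, 1, rng), BatchNorm2d(w), ReLU()]
        c_in = w
        for stage, c_out in enumerate((w, 2 * w, 4 * w, 8 * w)):
            for block in range(2):
                stride = 2 if (stage > 0 and block == 0 and extent >= 4) else 1
                layers.append(BasicBlock(c_in, c_out, stride, rng))
                extent = _out_extent(extent, stride)
                c_in = c_out
        layers.append(GlobalAvgPool())
        # zero-initialized head: the model starts as a pure-bias predictor
        self.head = Linear(8 * w, 1, rng, zero_init=True)
        layers.append(self.head)
        self.net = Sequential(*layers)

    def parameters(self):
        return self.net.parameters()

    def state_arrays(self):
        return self.net.state_arrays()

    def forward(self, x, train: bool = False):
        x = np.asarray(x, dtype=_F)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected input (N, {self.in_channels}, P, P), got {x.shape}")
        return self.net.forward(x, train)

    def backward(self, grad):
        return self.net.backward(np.asarray(grad, dtype=_F))

    def predict(self, x, batch_size: int = 1024) -> np.ndarray:
        """Inference-mode predictions, flattened to shape (N,)."""
        outs = [self.forward(x[i:i + batch_size], train=False)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs).ravel().astype(float)

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for a, s in zip(self.state_arrays(), state, strict=True):
            a[...] = s


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean-squared-error loss and its gradient w.r.t. the predictions."""
    diff = pred.ravel() - target.ravel()
    loss = float(np.mean(diff ** 2))
    grad = (2.0 / diff.size) * diff.reshape(pred.shape)
    return loss, grad.astype(_F)


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: list[dict], lr: float = 1e-5,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            if g is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p["value"] -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(_F)
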