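"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly what the Siamese variational auto-encoder needs:
strided 3x3/1x1 convolutions (im2col), batch normalization, ReLU,
dense layers, nearest-neighbour upsampling, sigmoid, and the
re-parameterizable convolution block that trains with parallel
3x3 + 1x1 + identity branches and fuses them into a single 3x3
convolution for inference.  Arrays are NCHW float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "Dense",
    "Flatten",
    "NearestUpsample",
    "Sequential",
    "RepVGGBlock",
    "Adam",
]

_BN_EPS = 1e-5


class Layer:
    """Base layer: named parameters, gradients, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def named_layers(self):
        yield "", self


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo))
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo), (n, c, h, w, ho, wo)


def _col2im(dcols: np.ndarray, shape_info: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w, ho, wo = shape_info
    dcols = dcols.reshape(n, c, k, k, ho, wo)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


class Conv2d(Layer):
    def __init__(
        self,
        in_c: int,
        out_c: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_c * kernel * kernel
        self.params["W"] = rng.standard_normal((out_c, in_c, kernel, kernel)) * np.sqrt(2.0 / fan_in)
        if bias:
            self.params["b"] = np.zeros(out_c)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.in_c, self.out_c = in_c, out_c
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, info = _im2col(x, self.kernel, self.stride, self.pad)
        self._cache = (cols, info)
        wf = self.params["W"].reshape(self.out_c, -1)
        y = np.einsum("oc,ncp->nop", wf, cols)
        n, _, _, _, ho, wo = info
        y = y.reshape(n, self.out_c, ho, wo)
        if "b" in self.params:
            y += self.params["b"][None, :, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, info = self._cache
        n, _, _, _, ho, wo = info
        dyf = dy.reshape(n, self.out_c, ho * wo)
        wf = self.params["W"].reshape(self.out_c, -1)
        self.grads["W"] += np.einsum("nop,ncp->oc", dyf, cols).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] += dy.sum(axis=(0, 2, 3))
        dcols = np.einsum("oc,nop->ncp", wf, dyf)
        return _col2im(dcols, info, self.kernel, self.stride, self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.1) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(n_ch)
        self.params["beta"] = np.zeros(n_ch)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + _BN_EPS)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std, train = self._cache
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        if not train:
            return dy * g / std[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (dxhat - sum_dxhat / m - xhat * sum_dxhat_xhat / m) / std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim)
        self.params["b"] = np.zeros(out_dim)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class NearestUpsample(Layer):
    def __init__(self, factor: int = 2) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.factor
        return x.repeat(f, axis=2).repeat(f, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.factor
        n, c, hf, wf = dy.shape
        return dy.reshape(n, c, hf // f, f, wf // f, f).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def named_layers(self):
        for i, layer in enumerate(self.layers):
            for sub, leaf in layer.named_layers():
                yield (f"{i}.{sub}" if sub else str(i)), leaf


class RepVGGBlock(Layer):
    """Re-parameterizable conv block: 3x3 + 1x1 (+ identity) then ReLU.

    During training the three parallel branches (each followed by batch
    normalization) are summed; :meth:`fuse` folds them into one 3x3
    convolution with bias whose output matches the multi-branch sum for
    every input, after which the block runs single-branch.
    """

    def __init__(
        self, in_c: int, out_c: int, stride: int = 1, rng: np.random.Generator | None = None
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_c, self.out_c, self.stride = in_c, out_c, stride
        self.conv3 = Conv2d(in_c, out_c, 3, stride, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out_c)
        self.conv1 = Conv2d(in_c, out_c, 1, stride, 0, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_c)
        self.bnid = BatchNorm2d(out_c) if (stride == 1 and in_c == out_c) else None
        self.relu = ReLU()
        self.fused_conv: Conv2d | None = None

    @property
    def is_fused(self) -> bool:
        return self.fused_conv is not None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.fused_conv is not None:
            return self.relu.forward(self.fused_conv.forward(x, train), train)
        y = self.bn3.forward(self.conv3.forward(x, train), train)
        y = y + self.bn1.forward(self.conv1.forward(x, train), train)
        if self.bnid is not None:
            y = y + self.bnid.forward(x, train)
        return self.relu.forward(y, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu.backward(dy)
        if self.fused_conv is not None:
            return self.fused_conv.backward(dy)
        dx = self.conv3.backward(self.bn3.backward(dy))
        dx = dx + self.conv1.backward(self.bn1.backward(dy))
        if self.bnid is not None:
            dx = dx + self.bnid.backward(dy)
        return dx

    def _fold_branch(self, kernel: np.ndarray, bn: BatchNorm2d) -> tuple[np.ndarray, np.ndarray]:
        std = np.sqrt(bn.running_var + _BN_EPS)
        scale = bn.params["gamma"] / std
        w = kernel * scale[:, None, None, None]
        b = bn.params["beta"] - bn.running_mean * scale
        return w, b

    def fuse(self) -> "RepVGGBlock":
        """Fold all branches into one 3x3 conv; idempotent."""
        if self.fused_conv is not None:
            return self
        w3, b3 = self._fold_branch(self.conv3.params["W"], self.bn3)
        k1 = np.zeros_like(w3)
        k1[:, :, 1:2, 1:2] = self.conv1.params["W"]
        w1, b1 = self._fold_branch(k1, self.bn1)
        w, b = w3 + w1, b3 + b1
        if self.bnid is not None:
            kid = np.zeros_like(w3)
            kid[np.arange(self.out_c), np.arange(self.out_c), 1, 1] = 1.0
            wid, bid = self._fold_branch(kid, self.bnid)
            w, b = w + wid, b + bid
        fused = Conv2d(self.in_c, self.out_c, 3, self.stride, 1, bias=True)
        fused.params["W"] = w
        fused.params["b"] = b
        fused.zero_grad()
        self.fused_conv = fused
        return self

    def zero_grad(self) -> None:
        for sub in self._sublayers():
            sub.zero_grad()

    def _sublayers(self) -> list[Layer]:
        if self.fused_conv is not None:
            return [self.fused_conv]
        subs: list[Layer] = [self.conv3, self.bn3, self.conv1, self.bn1]
        if self.bnid is not None:
            subs.append(self.bnid)
        return subs

    def named_layers(self):
        names = (
            ["fused"]
            if self.fused_conv is not None
            else ["conv3", "bn3", "conv1", "bn1"] + (["bnid"] if self.bnid is not None else [])
        )
        for name, sub in zip(names, self._sublayers()):
            yield name, sub


class Adam:
    """Adam optimizer over the leaf layers of a set of modules."""

    def __init__(
        self, modules: list[Layer], lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.modules = modules
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    def _leaves(self):
        for mod in self.modules:
            for _, leaf in mod.named_layers():
                yield leaf

    def zero_grad(self) -> None:
        for leaf in self._leaves():
            leaf.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for leaf in self._leaves():
            for name, p in leaf.params.items():
                g = leaf.grads[name]
                key = (id(leaf), name)
                m, v = self.state.get(key, (np.zeros_like(p), np.zeros_like(p)))
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self.state[key] = (m, v)
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
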