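"""Neural-network layers with explicit forward/backward passes.

Tensors are NCHW float32.  Each layer caches what its backward pass needs;
``backward`` consumes the upstream gradient and accumulates parameter
gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "CenterContextPool",
    "Linear",
]


class Param:
    """A trainable array with its gradient and momentum buffer."""

    __slots__ = ("data", "grad", "velocity", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.velocity = np.zeros_like(self.data)
        self.name = name


class Module:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def state_items(self) -> list[tuple[str, np.ndarray]]:
        """Name/array pairs for serialization (params + running stats)."""
        return [(p.name, p.data) for p in self.params()]


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        self.modules = list(modules)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy

    def params(self) -> list[Param]:
        return [p for m in self.modules for p in m.params()]

    def state_items(self) -> list[tuple[str, np.ndarray]]:
        return [it for m in self.modules for it in m.state_items()]


def _pad(x: np.ndarray, p: int, value: float = 0.0) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=value)


class Conv2d(Module):
    """2-D convolution (cross-correlation) via sliding windows + tensordot."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_ch), f"{name}.bias") if bias else None
        self.stride, self.pad, self.kernel = stride, pad, kernel

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        s, k = self.stride, self.kernel
        xp = _pad(x.astype(np.float32, copy=False), self.pad)
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = cols[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        self._cols, self._xshape, self._xpshape = cols, x.shape, xp.shape
        out = np.tensordot(cols, self.weight.data, axes=([1, 4, 5], [1, 2, 3]))
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))  # (N, O, Ho, Wo)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s, k = self.stride, self.kernel
        cols = self._cols
        self.weight.grad += np.einsum("nohw,nchwij->ocij", dy, cols, optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dcols = np.einsum("nohw,ocij->nchwij", dy, self.weight.data, optimize=True)
        dxp = np.zeros(self._xpshape, dtype=np.float32)
        Ho, Wo = dy.shape[2], dy.shape[3]
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dcols[:, :, :, :, i, j]
        p = self.pad
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        # padded input may extend past the last window; crop to input shape
        return dxp[:, :, : self._xshape[2], : self._xshape[3]]

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(ch), f"{name}.gamma")
        self.beta = Param(np.zeros(ch), f"{name}.beta")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.name = name

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return (self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]).astype(
            np.float32
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not train:
            return (dy * g * inv[None, :, None, None]).astype(np.float32)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        dx = (
            inv[None, :, None, None]
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            )
        )
        return dx.astype(np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state_items(self) -> list[tuple[str, np.ndarray]]:
        return super().state_items() + [
            (f"{self.name}.running_mean", self.running_mean),
            (f"{self.name}.running_var", self.running_var),
        ]


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, pad: int = 0) -> None:
        self.kernel = kernel
        self.stride = stride or kernel
        self.pad = pad

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s = self.kernel, self.stride
        xp = _pad(x, self.pad, value=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        N, C, Ho, Wo = win.shape[:4]
        flat = win.reshape(N, C, Ho, Wo, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, xp.shape, Ho, Wo)
        return np.ascontiguousarray(out.astype(np.float32))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        idx, xshape, xpshape, Ho, Wo = self._cache
        N, C = xshape[0], xshape[1]
        dxp = np.zeros(xpshape, dtype=np.float32)
        ai, aj = idx // k, idx % k
        rows = np.arange(Ho)[None, None, :, None] * s + ai
        cols = np.arange(Wo)[None, None, None, :] * s + aj
        n_idx = np.broadcast_to(np.arange(N)[:, None, None, None], idx.shape)
        c_idx = np.broadcast_to(np.arange(C)[None, :, None, None], idx.shape)
        np.add.at(dxp, (n_idx, c_idx, rows, cols), dy)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp[:, :, : xshape[2], : xshape[3]]


class GlobalAvgPool(Module):
    """Adaptive average pooling to 1x1; makes the head input-size agnostic."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return (np.broadcast_to(dy[:, :, None, None], self._shape) / (H * W)).astype(np.float32)


class CenterContextPool(Module):
    """Global average pooling concatenated with a central-time-band average.

    Emits 2C features per image: the mean over the whole map and the mean
    over the central fifth of the time axis (all rows).  A head on top can
    weight the labeled central second of a context window separately from
    its flanks — pure global pooling cannot localize the center at all.
    """

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        c0 = (2 * W) // 5
        c1 = max(c0 + 1, W - c0)
        self._cache = (x.shape, c0, c1)
        full = x.mean(axis=(2, 3))
        center = x[:, :, :, c0:c1].mean(axis=(2, 3))
        return np.concatenate([full, center], axis=1).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (N, C, H, W), c0, c1 = self._cache
        d_full = dy[:, :C]
        d_center = dy[:, C:]
        dx = np.broadcast_to(d_full[:, :, None, None], (N, C, H, W)) / (H * W)
        dx = dx.copy()
        dx[:, :, :, c0:c1] += d_center[:, :, None, None] / (H * (c1 - c0))
        return dx.astype(np.float32)


class Linear(Module):
    def __init__(
        self, in_f: int, out_f: int, rng: np.random.Generator | None = None, name: str = "fc"
    ) -> None:
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_f)
        self.weight = Param(rng.uniform(-bound, bound, (out_f, in_f)), f"{name}.weight")
        self.bias = Param(rng.uniform(-bound, bound, out_f), f"{name}.bias")

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return (dy @ self.weight.data).astype(np.float32)

    def params(self) -> list[Param]:
        return [self.weight, self.bias]
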