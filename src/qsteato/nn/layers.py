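"""Minimal numpy layers with manual backprop.

Enough machinery to train the tiny CNN backbone plus the hybrid/classical
heads on one CPU; not a general autodiff framework.  Every layer caches what
its backward pass needs during ``forward(train=True)``.
"""

from __future__ import annotations

import numpy as np

from ..quantum import QDIConfig, QDIParameters, qdi_forward_and_grad_batch, qdi_forward_batch


class Layer:
    """Base class: stateless unless it declares ``params``/``grads`` dicts."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / in_dim)
        self.params = {
            "W": rng.normal(0.0, scale, size=(in_dim, out_dim)),
            "b": np.zeros(out_dim),
        }

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        return grad * self._mask


class ScaledTanh(Layer):
    """x -> scale * tanh(x); with scale=pi it squashes features to (-pi, pi)."""

    def __init__(self, scale: float = 1.0) -> None:
        super().__init__()
        self.scale = scale

    def forward(self, x, train=False):
        t = np.tanh(x)
        if train:
            self._t = t
        return self.scale * t

    def backward(self, grad):
        return grad * self.scale * (1.0 - self._t**2)


def _im2col(xp: np.ndarray, k: int, stride: int, Ho: int, Wo: int) -> np.ndarray:
    B, C, _, _ = xp.shape
    cols = np.empty((B, C, k, k, Ho, Wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride]
    return cols.reshape(B, C * k * k, Ho * Wo)


def _col2im(cols: np.ndarray, shape, k: int, stride: int, Ho: int, Wo: int) -> np.ndarray:
    B, C, Hp, Wp = shape
    xp = np.zeros(shape, dtype=cols.dtype)
    cols = cols.reshape(B, C, k, k, Ho, Wo)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += cols[:, :, i, j]
    return xp


class Conv2d(Layer):
    """3x3-style convolution via im2col; stride doubles as downsampling."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 1, pad: int = 1) -> None:
        super().__init__()
        self.k, self.stride, self.pad = kernel, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, size=(out_ch, in_ch * kernel * kernel)),
            "b": np.zeros(out_ch),
        }

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        cols = _im2col(xp, k, s, Ho, Wo)
        out = np.einsum("oc,bcl->bol", self.params["W"], cols)
        out += self.params["b"][None, :, None]
        if train:
            self._cols, self._xshape, self._ho_wo = cols, xp.shape, (Ho, Wo)
            self._in_shape = x.shape
        return out.reshape(B, self.out_ch, Ho, Wo)

    def backward(self, grad):
        B = grad.shape[0]
        Ho, Wo = self._ho_wo
        g = grad.reshape(B, self.out_ch, Ho * Wo)
        self.grads["W"] = np.einsum("bol,bcl->oc", g, self._cols)
        self.grads["b"] = g.sum(axis=(0, 2))
        dcols = np.einsum("oc,bol->bcl", self.params["W"], g)
        dxp = _col2im(dcols, self._xshape, self.k, self.stride, Ho, Wo)
        p = self.pad
        _, _, H, W = self._in_shape
        return dxp[:, :, p : p + H, p : p + W]


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        B, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (H * W)


class QDILayer(Layer):
    """Data re-uploading quantum head; gradients via the parameter-shift rule."""

    def __init__(self, config: QDIConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.config = config
        self.params = {"theta": QDIParameters.random(config, rng).theta}

    def forward(self, x, train=False):
        params = QDIParameters(self.params["theta"])
        if train:
            self._x = x
        return qdi_forward_batch(x, params, self.config)

    def backward(self, grad):
        params = QDIParameters(self.params["theta"])
        # complex64 engine: parameter-shift is exact, so the only error is
        # ~1e-6 float rounding -- irrelevant for SGD but ~2x faster
        _, dtheta, dfeat = qdi_forward_and_grad_batch(
            self._x, params, self.config, dtype=np.complex64
        )
        self.grads["theta"] = np.einsum("bpqn,bn->pq", dtheta, grad)
        return np.einsum("bfn,bn->bf", dfeat, grad)


class Sequential(Layer):
    """Named composition; parameter names are dotted paths ``layer.param``."""

    def __init__(self, layers: list[tuple[str, Layer]]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x, train=False):
        for _, layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            if isinstance(layer, Sequential):
                for sub, arr in layer.named_params().items():
                    out[f"{name}.{sub}"] = arr
            else:
                for pname, arr in layer.params.items():
                    out[f"{name}.{pname}"] = arr
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            if isinstance(layer, Sequential):
                for sub, arr in layer.named_grads().items():
                    out[f"{name}.{sub}"] = arr
            else:
                for pname, arr in layer.grads.items():
                    out[f"{name}.{pname}"] = arr
        return out

    def set_params(self, named: dict[str, np.ndarray]) -> None:
        current = self.named_params()
        missing = set(current) - set(named)
        extra = set(named) - set(current)
        if missing or extra:
            raise ValueError(f"parameter schema mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, arr in named.items():
            if current[name].shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            current[name][...] = arr
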