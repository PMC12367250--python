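"""Minimal numpy CNN engine: the layers a 2D U-Net needs, with backprop.

All convolutions are lowered to GEMMs (im2col via stride tricks), including
their backward passes — the input gradient of a padded 3x3 correlation is
itself a correlation of the output gradient with the spatially flipped,
channel-transposed kernel, so no scatter-add is needed anywhere.  Arrays are
float32, NCHW.  Weight init is He et al.'s fan-in scheme; the optimizer is
SGD with Nesterov momentum.  Every layer caches what its backward pass needs;
`backward` must follow the matching `forward`.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base: parameterized layers expose params/grads dicts keyed by name."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H+k-1, W+k-1) padded input -> (B*H*W, C*k*k) patch matrix."""
    w = sliding_window_view(x, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    b, c, h, wd = w.shape[:4]
    return np.ascontiguousarray(w.transpose(0, 2, 3, 1, 4, 5)).reshape(b * h * wd, c * k * k)


def _conv2d_same(x: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Same-padded correlation. x (B,Cin,H,W), weight (Cout,Cin,k,k)."""
    k = weight.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = _im2col(xp, k)
    wmat = weight.reshape(weight.shape[0], -1)
    y = cols @ wmat.T
    b, _, h, wd = x.shape
    return y.reshape(b, h, wd, weight.shape[0]).transpose(0, 3, 1, 2)


class Conv2d(Layer):
    """k x k convolution, stride 1, same padding, optional bias."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = c_in * k * k
        w = rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)
        self.params = {"w": w.astype(np.float32), "b": np.zeros(c_out, dtype=np.float32)}
        self.k = k
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = _conv2d_same(x, self.params["w"])
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, w, k = self._x, self.params["w"], self.k
        p = k // 2
        self.grads["b"] = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        # dW: correlate input patches with dy
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(xp, k)                     # (BHW, Cin*k*k)
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, w.shape[0])  # (BHW, Cout)
        self.grads["w"] = (dyf.T @ cols).reshape(w.shape).astype(np.float32)
        # dX: correlate dy with flipped, channel-transposed kernel
        w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)       # (Cin, Cout, k, k)
        return _conv2d_same(dy, np.ascontiguousarray(w_flip))


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01) -> None:
        super().__init__()
        self.a = negative_slope
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.a * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.a * dy)


class MaxPool2x2(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._idx: Optional[np.ndarray] = None
        self._shape: Optional[Tuple[int, ...]] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 needs even spatial dims")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(b, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        out = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(out, self._idx[..., None], dy[..., None], axis=-1)
        out = out.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(b, c, h, w)


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution, stride 2 (the U-Net up-sampling step)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.standard_normal((c_in, c_out, 2, 2)) * np.sqrt(2.0 / c_in)
        self.params = {"w": w.astype(np.float32), "b": np.zeros(c_out, dtype=np.float32)}
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w = self.params["w"]
        # (B,Cin,H,W) x (Cin,Cout,2,2) -> (B,H,W,Cout,2,2)
        y = np.tensordot(x, w, axes=([1], [0]))
        b, h, wd = x.shape[0], x.shape[2], x.shape[3]
        y = y.transpose(0, 3, 1, 4, 2, 5).reshape(b, w.shape[1], 2 * h, 2 * wd)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, w = self._x, self.params["w"]
        b, cin, h, wd = x.shape
        cout = w.shape[1]
        self.grads["b"] = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        blocks = dy.reshape(b, cout, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
        # dW[cin,cout,i,j] = sum_bhw x[b,cin,h,w] * blocks[b,h,w,cout,i,j]
        self.grads["w"] = np.tensordot(
            x, blocks, axes=([0, 2, 3], [0, 1, 2])).astype(np.float32)
        # dX[b,cin,h,w] = sum_{cout,i,j} blocks * w
        dx = np.tensordot(blocks, w, axes=([3, 4, 5], [1, 2, 3]))
        return dx.transpose(0, 3, 1, 2).astype(np.float32)


class ConvBlock(Layer):
    """Two same-padded kxk convs, each followed by LeakyReLU."""

    def __init__(self, c_in: int, filters: Tuple[int, int], rng: np.random.Generator,
                 negative_slope: float = 0.01, k: int = 3) -> None:
        super().__init__()
        self.conv1 = Conv2d(c_in, filters[0], k, rng)
        self.act1 = LeakyReLU(negative_slope)
        self.conv2 = Conv2d(filters[0], filters[1], k, rng)
        self.act2 = LeakyReLU(negative_slope)
        self.sub = [self.conv1, self.act1, self.conv2, self.act2]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.sub:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.sub):
            dy = layer.backward(dy)
        return dy


class SGDNesterov:
    """SGD with Nesterov momentum: v <- mu*v + g; p <- p - lr*(g + mu*v)."""

    def __init__(self, layers: List[Layer], momentum: float = 0.99) -> None:
        self.layers = [l for l in _walk(layers) if l.params]
        self.momentum = momentum
        self.velocity = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self, lr: float) -> None:
        mu = self.momentum
        for layer, vel in zip(self.layers, self.velocity):
            for k, p in layer.params.items():
                g = layer.grads[k]
                v = vel[k]
                v *= mu
                v += g
                p -= lr * (g + mu * v)


def _walk(layers) -> List[Layer]:
    out: List[Layer] = []
    for l in layers:
        if isinstance(l, ConvBlock):
            out.extend(l.sub)
        elif isinstance(l, Layer):
            out.append(l)
    return out


def collect_params(layers) -> Dict[str, np.ndarray]:
    """Flat name->array view over all parameters (for checkpointing)."""
    out = {}
    for i, l in enumerate(_walk(layers)):
        for k, v in l.params.items():
            out[f"layer{i:03d}.{k}"] = v
    return out


def load_params(layers, flat: Dict[str, np.ndarray]) -> None:
    for i, l in enumerate(_walk(layers)):
        for k in l.params:
            l.params[k] = np.asarray(flat[f"layer{i:03d}.{k}"], dtype=np.float32)
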